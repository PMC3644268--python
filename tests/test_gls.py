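"""Aggregated design matrix, GLS fit and hat-matrix diagnostics."""

import numpy as np
import pandas as pd
import pytest

from nmadiag import (
    NetworkMetaAnalysis,
    build_design_matrix,
    fit_network,
    hat_contributions,
    parse_contrast_table,
    study_contribution_split,
)
from nmadiag.scenarios import ScenarioSpec, make_scenario

from conftest import (
    connected_edge_subsets,
    effective_resistance,
    one_stage_fit,
    random_network,
    three_arm_table,
)


def table(rows):
    return pd.DataFrame(rows, columns=["study", "treat1", "treat2", "effect", "se"])


class TestDesignMatrix:
    def test_three_design_example(self):
        net = parse_contrast_table(
            table([("s1", "A0", "A1", 0.0, 1.0), ("s2", "A0", "A2", 0.0, 1.0),
                   ("s3", "A1", "A2", 0.0, 1.0)])
        )
        model = build_design_matrix(net)
        np.testing.assert_array_equal(model.X_a, [[1, 0], [0, 1], [-1, 1]])

    def test_with_three_arm_design_appends_two_rows(self):
        rows = table(
            [("s1", "A0", "A1", 0.0, 1.0), ("s2", "A0", "A1", 0.0, 1.0),
             ("s3", "A0", "A2", 0.0, 1.0), ("s4", "A1", "A2", 0.0, 1.0)]
        )
        arm = pd.DataFrame(
            {"study": ["s5"] * 3, "treatment": ["A0", "A1", "A2"], "var": [1.0] * 3}
        )
        rows = pd.concat(
            [rows, table([("s5", "A0", "A1", 0.0, np.sqrt(2)),
                          ("s5", "A0", "A2", 0.0, np.sqrt(2))])]
        )
        model = build_design_matrix(parse_contrast_table(rows, arm))
        assert model.X_a.shape == (5, 2)
        sl = model.design_slices["A0:A1:A2"]
        np.testing.assert_array_equal(model.X_a[sl], [[1, 0], [0, 1]])
        assert model.row_labels[sl.start:sl.stop] == ("A0:A1*", "A0:A2*")

    def test_single_design(self):
        model = build_design_matrix(
            parse_contrast_table(table([("s1", "A", "B", 0.0, 1.0)]))
        )
        np.testing.assert_array_equal(model.X_a, [[1.0]])


class TestFit:
    def test_fig1a_fitted_contrasts(self, fig1a_results):
        """Perturbing design 1:2 by 5 gives the known fitted contrast vector."""
        np.testing.assert_allclose(
            fig1a_results.fitted_contrasts.to_numpy(),
            [3.167, 1.333, 0.500, -1.834, -0.500, -0.166, -0.333, -0.167],
            atol=0.005,
        )

    def test_triangle_hand_minimization(self, triangle_results):
        """min (1-a)^2 + b^2 + (b-a)^2 gives a=2/3, b=1/3."""
        assert triangle_results.theta_net["1:2"] == pytest.approx(2 / 3)
        assert triangle_results.theta_net["1:3"] == pytest.approx(1 / 3)

    def test_consistent_inputs_recovered_exactly(self):
        net = random_network(seed=5, n_studies=1)
        res = NetworkMetaAnalysis(net).fit()
        model = res.aggregated
        theta = np.arange(1.0, model.X_a.shape[1] + 1)
        y_consistent = model.X_a @ theta
        from dataclasses import replace

        model2 = replace(model, theta_dir_stacked=y_consistent)
        fit2 = fit_network(model2)
        np.testing.assert_allclose(fit2.theta_net, theta, atol=1e-10)

    def test_one_stage_two_stage_equivalence(self):
        """Fitting studies directly equals fitting pooled designs (1e-8)."""
        for seed in (0, 1, 2):
            net = random_network(seed=seed, n_studies=3, het_sd=0.4)
            res = NetworkMetaAnalysis(net).fit()
            theta1, cov1 = one_stage_fit(net)
            np.testing.assert_allclose(res.network_fit.theta_net, theta1, atol=1e-8)
            np.testing.assert_allclose(res.network_fit.cov_net, cov1, atol=1e-8)

    def test_one_stage_two_stage_equivalence_with_multiarm(self):
        rows, arm = three_arm_table(effects=(0.4, 0.9))
        extra = table(
            [("t1", "A", "B", 0.8, 0.5), ("t2", "A", "B", 0.6, 0.9),
             ("t3", "B", "C", 0.3, 0.6), ("t4", "A", "C", 1.1, 0.8)]
        )
        net = parse_contrast_table(pd.concat([rows, extra]), arm)
        res = NetworkMetaAnalysis(net).fit()
        theta1, cov1 = one_stage_fit(net)
        np.testing.assert_allclose(res.network_fit.theta_net, theta1, atol=1e-8)
        np.testing.assert_allclose(res.network_fit.cov_net, cov1, atol=1e-8)

    def test_network_reference_invariance_of_contrasts(self):
        """Relabeling treatments (changing A_0) leaves contrast estimates fixed."""
        base = table(
            [("s1", "1", "2", 0.7, 1.0), ("s2", "2", "3", 0.1, 0.5),
             ("s3", "1", "3", 0.5, 0.8), ("s4", "3", "4", -0.2, 0.6),
             ("s5", "1", "4", 0.4, 0.9)]
        )
        mapping = {"1": "z", "2": "a", "3": "m", "4": "b"}
        relabeled = base.copy()
        relabeled["treat1"] = relabeled["treat1"].map(mapping)
        relabeled["treat2"] = relabeled["treat2"].map(mapping)
        r1 = NetworkMetaAnalysis.from_dataframe(base).fit()
        r2 = NetworkMetaAnalysis.from_dataframe(relabeled).fit()
        t1 = r1.contrast_table()
        t2 = r2.contrast_table()
        for _, row in t1.iterrows():
            a, b = mapping[row["treat1"]], mapping[row["treat2"]]
            m = t2[(t2["treat1"] == min(a, b)) & (t2["treat2"] == max(a, b))]
            sign = 1.0 if (min(a, b), max(a, b)) == (a, b) else -1.0
            assert float(m["estimate"].iloc[0]) == pytest.approx(
                sign * row["estimate"], abs=1e-10
            )
            assert float(m["se"].iloc[0]) == pytest.approx(row["se"], abs=1e-10)


class TestHatMatrix:
    def test_fig1a_diagonal_drivers(self, fig1a_results):
        """Bridging-cycle designs drive 70%, twice-paralleled designs 53%."""
        H = fig1a_results.hat_matrix
        for d in ("1:6", "3:4"):
            assert H.loc[d, d] == pytest.approx(0.70, abs=0.005)
        for d in ("1:3", "4:6"):
            assert H.loc[d, d] == pytest.approx(8 / 15, abs=1e-10)

    def test_six_cycle_diagonal(self):
        res = NetworkMetaAnalysis(make_scenario(ScenarioSpec("fig3_d"))).fit()
        H = res.hat_matrix
        for d in H.index:
            assert H.loc[d, d] == pytest.approx(5 / 6, abs=1e-10)

    def test_single_design_hat_is_one(self):
        res = NetworkMetaAnalysis.from_dataframe(
            table([("s1", "A", "B", 0.3, 1.0)])
        ).fit()
        np.testing.assert_allclose(res.network_fit.H, [[1.0]])

    def test_projection_invariants(self):
        """H idempotent, trace T, diagonal in [0,1], entries in [-1,1], HX=X."""
        for spec in (ScenarioSpec("fig1_a"), ScenarioSpec("fig3_e")):
            res = NetworkMetaAnalysis(make_scenario(spec)).fit()
            H, X = res.network_fit.H, res.aggregated.X_a
            np.testing.assert_allclose(H @ H, H, atol=1e-10)
            assert np.trace(H) == pytest.approx(res.data.n_basic_parameters)
            assert np.all(np.diag(H) > -1e-12) and np.all(np.diag(H) < 1 + 1e-12)
            assert np.all(np.abs(H) <= 1 + 1e-12)
            np.testing.assert_allclose(H @ X, X, atol=1e-10)

    def test_percent_formatting_rounds_half_away_from_zero(self, fig1a_results):
        pct = fig1a_results.hat_percent()
        assert pct.loc["1:6", "1:6"] == 70
        assert pct.loc["1:3", "1:3"] == 53  # 8/15 = 53.33%
        raw = hat_contributions(fig1a_results.network_fit)
        assert raw.loc["1:3", "1:3"] == pytest.approx(8 / 15)

    def test_effective_resistance_oracle(self):
        """Diagonal hat entries equal the direct-vs-indirect precision weight.

        For every connected graph with at most five edges, h_dd must equal
        (1/V_d) / (1/V_d + 1/R_ind), with R_ind the effective resistance
        between d's endpoints after deleting edge d (resistance = variance).
        """
        rng = np.random.default_rng(42)
        n_checked = 0
        for edges in connected_edge_subsets(max_edges=5, n_nodes=5):
            variances = rng.uniform(0.5, 2.0, size=len(edges))
            rows = [
                (f"s{k}", a, b, 0.0, float(np.sqrt(v)))
                for k, ((a, b), v) in enumerate(zip(edges, variances))
            ]
            net = parse_contrast_table(table(rows))
            res = NetworkMetaAnalysis(net).fit()
            H = res.hat_matrix
            nodes = sorted({t for e in edges for t in e})
            for (a, b), v in zip(edges, variances):
                others = [e for e in edges if e != (a, b)]
                other_vars = [w for e, w in zip(edges, variances) if e != (a, b)]
                r_ind = effective_resistance(nodes, others, other_vars, a, b)
                expect = 1.0 if np.isinf(r_ind) else (1 / v) / (1 / v + 1 / r_ind)
                d = f"{min(a, b)}:{max(a, b)}"
                assert H.loc[d, d] == pytest.approx(expect, abs=1e-9)
            n_checked += 1
        assert n_checked > 500  # exhaustive over <=5-edge subsets of K5


class TestStudySplit:
    def test_equal_variance_split(self, fig1a_results):
        """Design weight w with two equal studies splits as (w/2, w/2)."""
        net = random_network(seed=3, n_studies=2)
        res = NetworkMetaAnalysis(net).fit()
        d = res.data.designs[0]
        shares = study_contribution_split(res.network_fit, d)
        h = res.hat_matrix.loc[d.design_id, d.design_id]
        assert sum(shares.values()) == pytest.approx(h)
        a, b = shares.values()
        assert a == pytest.approx(b) == pytest.approx(h / 2)

    def test_unequal_shares_sum_to_design_entry(self):
        rows = table(
            [("s1", "A", "B", 0.2, 0.4), ("s2", "A", "B", 0.1, 1.3),
             ("s3", "B", "C", 0.0, 1.0), ("s4", "A", "C", 0.1, 1.0)]
        )
        res = NetworkMetaAnalysis.from_dataframe(rows).fit()
        shares = res.study_contributions("A:B")
        assert sum(shares.values()) == pytest.approx(
            res.hat_matrix.loc["A:B", "A:B"]
        )
        assert shares["s1"] > shares["s2"]  # precision-proportional

    def test_single_study_design_gets_full_weight(self, fig1a_results):
        shares = fig1a_results.study_contributions("1:2")
        assert list(shares.values())[0] == pytest.approx(
            fig1a_results.hat_matrix.loc["1:2", "1:2"]
        )

    def test_multiarm_design_unsupported(self):
        rows, arm = three_arm_table()
        extra = table(
            [("t1", "A", "B", 0.8, 0.5), ("t2", "B", "C", 0.3, 0.6)]
        )
        net = parse_contrast_table(pd.concat([rows, extra]), arm)
        res = NetworkMetaAnalysis(net).fit()
        with pytest.raises(ValueError, match="multi-arm"):
            res.study_contributions("A:B:C")
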