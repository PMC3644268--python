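"""Model/Results interface tying the two-stage pipeline together.

`NetworkMetaAnalysis` is constructed from contrast-level data (a
DataFrame, a CSV file, or prebuilt :class:`~nmadiag.data.NetworkData`);
``fit()`` runs per-design pooling and the aggregate GLS fit and returns
an :class:`NMAResults` carrying the basic-parameter estimates and their
covariance, the hat matrix, the Q decomposition, design detaching, the
Q-difference matrix and the net heat plot.
"""

from __future__ import annotations

import json
from functools import cached_property

import numpy as np
import pandas as pd

from . import detach as _detach
from . import gls as _gls
from . import netheat as _netheat
from .data import NetworkData, parse_contrast_table, read_contrast_table
from .pooling import pool_design
from .qstats import QDecomposition, decompose_q

__all__ = ["NetworkMetaAnalysis", "NMAResults"]

STATS_SCHEMA_VERSION = 1


class NetworkMetaAnalysis:
    """Fixed-effects network meta-analysis of contrast-level data.

    Examples
    --------
    >>> from nmadiag import NetworkMetaAnalysis
    >>> from nmadiag.scenarios import ScenarioSpec, make_scenario
    >>> net = make_scenario(ScenarioSpec("fig1_a", "1:2", 5.0))
    >>> res = NetworkMetaAnalysis(net).fit()
    >>> round(res.q_decomposition.Q_inc, 2)
    9.17
    """

    def __init__(self, data: NetworkData):
        self.data = data

    @classmethod
    def from_dataframe(
        cls, rows: pd.DataFrame, arm_variances: pd.DataFrame | None = None
    ) -> "NetworkMetaAnalysis":
        return cls(parse_contrast_table(rows, arm_variances))

    @classmethod
    def from_csv(cls, path, arm_vars_path=None, sep=None) -> "NetworkMetaAnalysis":
        return cls(read_contrast_table(path, arm_vars_path, sep=sep))

    def fit(self) -> "NMAResults":
        directs = tuple(pool_design(d) for d in self.data.designs)
        model = _gls.build_design_matrix(self.data, directs)
        fit = _gls.fit_network(model)
        return NMAResults(self, fit)


class NMAResults:
    """Results of the two-stage fixed-effects network meta-analysis."""

    def __init__(self, model: NetworkMetaAnalysis, fit: _gls.NetworkFit):
        self.model = model
        self.network_fit = fit
        self.aggregated = fit.model

    # --- estimates -------------------------------------------------------

    @property
    def data(self) -> NetworkData:
        return self.model.data

    @property
    def reference(self) -> str:
        return self.data.reference

    @cached_property
    def theta_net(self) -> pd.Series:
        """Basic parameters: each treatment versus the network reference."""
        labels = [f"{self.reference}:{t}" for t in self.aggregated.col_labels]
        return pd.Series(self.network_fit.theta_net, index=labels, name="theta_net")

    @cached_property
    def cov_params(self) -> pd.DataFrame:
        idx = list(self.theta_net.index)
        return pd.DataFrame(self.network_fit.cov_net, index=idx, columns=idx)

    @cached_property
    def se(self) -> pd.Series:
        return pd.Series(
            self.network_fit.se_net, index=self.theta_net.index, name="se"
        )

    @cached_property
    def fitted_contrasts(self) -> pd.Series:
        """Network estimates for every observed design-contrast."""
        return pd.Series(
            self.network_fit.fitted,
            index=list(self.aggregated.row_labels),
            name="fitted",
        )

    def contrast_table(self) -> pd.DataFrame:
        """League-style table: estimate and SE for every treatment pair."""
        treatments = list(self.data.treatments)
        cols = {t: i for i, t in enumerate(self.aggregated.col_labels)}
        theta = self.network_fit.theta_net
        cov = self.network_fit.cov_net
        rows = []
        for i, a in enumerate(treatments):
            for b in treatments[i + 1:]:
                c = np.zeros(len(cols))
                if b != self.reference:
                    c[cols[b]] = 1.0
                if a != self.reference:
                    c[cols[a]] = -1.0
                est = float(c @ theta)
                se = float(np.sqrt(c @ cov @ c))
                rows.append((a, b, est, se))
        return pd.DataFrame(rows, columns=["treat1", "treat2", "estimate", "se"])

    # --- diagnostics -----------------------------------------------------

    @cached_property
    def hat_matrix(self) -> pd.DataFrame:
        return _gls.hat_contributions(self.network_fit)

    def hat_percent(self) -> pd.DataFrame:
        return _gls.hat_contributions(self.network_fit, percent=True)

    def study_contributions(self, design_id: str) -> dict[str, float]:
        return _gls.study_contribution_split(
            self.network_fit, self.data.design(design_id)
        )

    @cached_property
    def q_decomposition(self) -> QDecomposition:
        return decompose_q(self.data, self.network_fit, self.aggregated.directs)

    @cached_property
    def detachable_designs(self) -> list[str]:
        return _detach.detachable_designs(self.data)

    def detach(self, design_id: str) -> _detach.DetachResult:
        return _detach.detach_design(self.aggregated, design_id)

    def detach_all(self) -> dict[str, _detach.DetachResult]:
        return {d: self.detach(d) for d in self.detachable_designs}

    @cached_property
    def q_diff(self) -> _detach.QDiffMatrix:
        return _detach.q_diff_matrix(self.aggregated, self.q_decomposition)

    def net_heat_layout(
        self, color_cap: float = _netheat.DEFAULT_COLOR_CAP, cluster: bool = True
    ) -> _netheat.NetHeatLayout:
        return _netheat.build_layout(
            self.q_diff, self.hat_matrix, color_cap=color_cap, cluster=cluster
        )

    def plot_net_heat(
        self,
        out,
        color_cap: float = _netheat.DEFAULT_COLOR_CAP,
        cluster: bool = True,
        format: str | None = None,
    ):
        """Render the net heat plot to a file; returns the path."""
        layout = self.net_heat_layout(color_cap=color_cap, cluster=cluster)
        return _netheat.render_netheat(layout, out, format=format)

    # --- reporting -------------------------------------------------------

    def to_stats_dict(self) -> dict:
        """JSON-serializable summary (stable schema, full precision)."""
        q = self.q_decomposition
        detach_summary = {}
        for did in self.detachable_designs:
            r = self.detach(did)
            detach_summary[did] = {"Q": r.Q_inc_detached, "df": r.df, "p": r.p}
        return {
            "schema_version": STATS_SCHEMA_VERSION,
            "reference": self.reference,
            "treatments": list(self.data.treatments),
            "n_studies": self.data.n_studies,
            "n_designs": self.data.n_designs,
            "theta_net": {
                k: {"estimate": float(v), "se": float(s)}
                for (k, v), s in zip(self.theta_net.items(), self.se)
            },
            "contrasts": self.contrast_table().to_dict(orient="records"),
            "direct_estimates": {
                d.design_id: {
                    "theta_dir": d.theta_dir.tolist(),
                    "V_dir": d.V_dir.tolist(),
                }
                for d in self.aggregated.directs
            },
            "hat_matrix": {
                "labels": list(self.aggregated.row_labels),
                "values": self.network_fit.H.tolist(),
            },
            "q": q.as_dict(),
            "detach": detach_summary,
            "detachable_designs": self.detachable_designs,
        }

    def to_stats_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_stats_dict(), indent=indent)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        """Plain-text summary table (p-values shown to three decimals)."""
        q = self.q_decomposition
        lines = []
        add = lines.append
        add("Fixed-effects network meta-analysis")
        add("=" * 60)
        add(
            f"treatments: {self.data.n_treatments}  designs: {self.data.n_designs}"
            f"  studies: {self.data.n_studies}  reference: {self.reference}"
        )
        add("")
        add("Basic parameters (vs reference)")
        add(f"{'contrast':>12} {'estimate':>10} {'se':>8}")
        for (k, v), s in zip(self.theta_net.items(), self.se):
            add(f"{k:>12} {v:>10.4f} {s:>8.4f}")
        add("")
        add("Cochran's Q decomposition")
        add(f"{'':>8} {'Q':>8} {'df':>4} {'p':>7}")
        for name, Q, df, p in [
            ("Q_net", q.Q_net, q.df_net, q.p_net),
            ("Q_het", q.Q_het, q.df_het, q.p_het),
            ("Q_inc", q.Q_inc, q.df_inc, q.p_inc),
        ]:
            add(f"{name:>8} {Q:>8.2f} {df:>4d} {p:>7.3f}")
        if q.df_inc == 0:
            add("note: inconsistency unassessable (no loops)")
        multi = [d.design_id for d in self.data.designs if len(d.studies) > 1]
        if multi:
            add("")
            add("Within-design heterogeneity (designs with >1 study)")
            add(f"{'design':>16} {'Q':>8} {'df':>4} {'p':>7}")
            for did in multi:
                Q, df, p = q.per_design_het[did]
                add(f"{did:>16} {Q:>8.2f} {df:>4d} {p:>7.3f}")
        return "\n".join(lines)
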