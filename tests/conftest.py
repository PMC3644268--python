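"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from nmadiag import NetworkMetaAnalysis
from nmadiag.scenarios import ScenarioSpec, make_scenario, random_topology, simulate_network


@pytest.fixture(scope="session")
def fig1a_results():
    """The eight-design illustrative network, perturbation 5 on design 1:2."""
    net = make_scenario(ScenarioSpec("fig1_a", "1:2", 5.0))
    return NetworkMetaAnalysis(net).fit()


@pytest.fixture(scope="session")
def triangle_results():
    """Triangle network with direct estimates (1, 0, 0), unit variances."""
    net = make_scenario(ScenarioSpec("triangle", "1:2", 1.0))
    return NetworkMetaAnalysis(net).fit()


def random_network(seed, het_sd=0.0, n_studies=2, n_treatments=6, extra_edges=3):
    """A reproducible random two-arm network with simulated study data."""
    rng = np.random.default_rng(seed)
    topo = random_topology(rng, n_treatments=n_treatments, extra_edges=extra_edges)
    theta = {str(i + 1): float(rng.normal(0, 1)) for i in range(n_treatments)}
    return simulate_network(
        topo,
        theta=theta,
        het_sd=het_sd,
        n_studies_per_design=n_studies,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# --- independent oracles -------------------------------------------------


def one_stage_fit(net):
    """Study-level GLS oracle: fit model (1) directly on the studies.

    Independent of the package's two-stage path: builds the study-level
    design matrix and solves the normal equations from scratch.
    """
    cols = {t: j for j, t in enumerate(net.treatments[1:])}
    rows, y_parts, v_blocks = [], [], []
    for d in net.designs:
        for s in d.studies:
            for ref, t in s.contrasts:
                r = np.zeros(len(cols))
                r[cols[t]] = 1.0
                if ref != net.reference:
                    r[cols[ref]] = -1.0
                rows.append(r)
            y_parts.append(s.y)
            v_blocks.append(s.cov)
    X = np.vstack(rows)
    y = np.concatenate(y_parts)
    V = scipy.linalg.block_diag(*v_blocks)
    Vinv = np.linalg.inv(V)
    A = X.T @ Vinv @ X
    theta = np.linalg.solve(A, X.T @ Vinv @ y)
    return theta, np.linalg.inv(A)


def effective_resistance(nodes, edges, variances, a, b):
    """Two-point effective resistance with edge resistances = variances.

    Returns ``inf`` if a and b are in different components.  Computed via
    the weighted-Laplacian pseudo-inverse.
    """
    idx = {t: i for i, t in enumerate(sorted(nodes))}
    n = len(idx)
    L = np.zeros((n, n))
    for (u, v), var in zip(edges, variances):
        w = 1.0 / var
        i, j = idx[u], idx[v]
        L[i, i] += w
        L[j, j] += w
        L[i, j] -= w
        L[j, i] -= w
    # component check
    import networkx as nx

    g = nx.Graph(edges)
    g.add_nodes_from(nodes)
    if not (g.has_node(a) and g.has_node(b)) or not nx.has_path(g, a, b):
        return np.inf
    Lp = np.linalg.pinv(L, hermitian=True)
    i, j = idx[a], idx[b]
    return float(Lp[i, i] + Lp[j, j] - 2 * Lp[i, j])


def connected_edge_subsets(max_edges=5, n_nodes=5):
    """All connected edge subsets of K_{n_nodes} with at most max_edges."""
    import networkx as nx

    labels = [str(i + 1) for i in range(n_nodes)]
    all_edges = list(itertools.combinations(labels, 2))
    for k in range(1, max_edges + 1):
        for subset in itertools.combinations(all_edges, k):
            g = nx.Graph(subset)
            if nx.is_connected(g):
                yield subset


def relabel_contrast_table(table, mapping, arm_vars=None):
    """Rename treatments in a contrast (and arm-variance) table."""
    t = table.copy()
    t["treat1"] = t["treat1"].map(mapping)
    t["treat2"] = t["treat2"].map(mapping)
    if arm_vars is None:
        return t, None
    a = arm_vars.copy()
    a["treatment"] = a["treatment"].map(mapping)
    return t, a


def three_arm_table(effects=(0.5, 0.8), study="s3arm"):
    """A consistent three-arm study as all-pairs rows plus arm variances."""
    yab, yac = effects
    rows = pd.DataFrame(
        {
            "study": [study] * 3,
            "treat1": ["A", "A", "B"],
            "treat2": ["B", "C", "C"],
            "effect": [yab, yac, yac - yab],
            "se": [np.sqrt(2.0)] * 3,
        }
    )
    arm = pd.DataFrame(
        {"study": [study] * 3, "treatment": ["A", "B", "C"], "var": [1.0, 1.0, 1.0]}
    )
    return rows, arm
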