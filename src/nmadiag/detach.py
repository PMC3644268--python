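"""Single-design detaching and the Q-difference matrix.

Detaching design d adds N_d - 1 deviation parameters (indicator columns
for d's contrast rows) to the aggregated model and refits.  The
remaining-inconsistency statistic

    Q_(d)^inc = R_(d)' V_a^-1 R_(d)

uses residuals identical to a consistency model fitted with design d's
studies held out; d's own residual block is exactly zero.  Comparing the
per-design summands before and after yields

    Q^diff_{d',d} = Q_{d'}^inc - Q_{d'}^{(d)inc},

the matrix behind the net heat plot.

Designs sharing fewer than two treatments with the rest of the network,
or whose removal would split it, carry no assessable inconsistency and
are not detachable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .data import NetworkData, design_graph
from .gls import AggregatedModel
from .qstats import QDecomposition, chi2_pvalue, q_dof

__all__ = ["DetachResult", "QDiffMatrix", "detachable_designs", "detach_design", "q_diff_matrix"]

_ZERO_TOL = 1e-10


@dataclass(frozen=True)
class DetachResult:
    """Refit with one design's effect freed from the consistency constraints."""

    design_id: str
    theta_net: np.ndarray
    theta_dir_ind: np.ndarray
    residuals: np.ndarray
    Q_inc_detached: float
    df: int
    p: float
    residual_components: dict[str, float]


@dataclass(frozen=True)
class QDiffMatrix:
    """Q^diff_{d',d} over detachable designs.

    ``values``: rows are design-contrasts of detachable designs (multi-arm
    designs contribute one starred row per contrast), columns are
    detachable designs.  ``diagonal`` holds the per-design inconsistency
    summands Q_{d'}^inc; ``design_rows`` maps each design to its rows.
    """

    values: pd.DataFrame
    diagonal: dict[str, float]
    design_rows: dict[str, list[str]]

    @property
    def row_labels(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_labels(self) -> list[str]:
        return list(self.values.columns)

    def design_level(self) -> pd.DataFrame:
        """Square design-by-design matrix (contrast rows summed per design)."""
        rows = {
            d: self.values.loc[labels].sum(axis=0)
            for d, labels in self.design_rows.items()
        }
        return pd.DataFrame(rows).T.loc[self.col_labels, self.col_labels]


def detachable_designs(net: NetworkData) -> list[str]:
    """Designs whose detachment yields an assessable inconsistency model.

    A design is detachable iff at least two of its treatments occur in
    other designs and those shared treatments stay mutually connected
    after removing all the design's studies.
    """
    out = []
    for d in net.designs:
        rest = nx.MultiGraph()
        for other in net.designs:
            if other.design_id == d.design_id:
                continue
            for a, b in itertools.combinations(other.treatments, 2):
                rest.add_edge(a, b, design=other.design_id)
        shared = [t for t in d.treatments if t in rest.nodes]
        if len(shared) < 2:
            continue
        comps = list(nx.connected_components(rest))
        if any(set(shared) <= c for c in comps):
            out.append(d.design_id)
    return out


def _detached_residuals(model: AggregatedModel, design_id: str):
    """Residuals of the GLS fit of the extended model (12)."""
    sl = model.design_slices[design_id]
    n = model.n_rows
    extra = np.zeros((n, sl.stop - sl.start))
    for j, i in enumerate(range(sl.start, sl.stop)):
        extra[i, j] = 1.0
    X = np.hstack([model.X_a, extra])
    Vinv = np.linalg.solve(model.V_a, np.eye(n))
    Vinv = (Vinv + Vinv.T) / 2.0
    A = X.T @ Vinv @ X
    # pinv: the extended model may be saturated or not fully identifiable;
    # residuals depend only on the column space, which pinv handles.
    theta = np.linalg.pinv(A, hermitian=True) @ (X.T @ Vinv @ y_of(model))
    resid = y_of(model) - X @ theta
    resid[np.abs(resid) < _ZERO_TOL] = 0.0
    resid[sl] = 0.0  # exact by construction
    return theta, resid, Vinv


def y_of(model: AggregatedModel) -> np.ndarray:
    return model.theta_dir_stacked


def detach_design(model: AggregatedModel, design_id: str) -> DetachResult:
    """Fit model (12) with deviation parameters for one design.

    Raises ``ValueError`` if the design is not detachable, naming the
    violated rule.
    """
    net = model.net
    if design_id not in model.design_slices:
        raise KeyError(design_id)
    if design_id not in detachable_designs(net):
        d = net.design(design_id)
        g = design_graph(net)
        shared = [
            t
            for t in d.treatments
            if any(k["design"] != design_id for _, _, k in g.edges(t, data=True))
        ]
        if len(shared) < 2:
            reason = "fewer than two of its treatments occur in other designs"
        else:
            reason = "removing its studies would split the network"
        raise ValueError(f"design {design_id} is not detachable: {reason}")

    sl = model.design_slices[design_id]
    theta, resid, Vinv = _detached_residuals(model, design_id)
    T = model.X_a.shape[1]
    q = float(resid @ Vinv @ resid)
    q = 0.0 if q < _ZERO_TOL else q

    components: dict[str, float] = {}
    direct_by_id = {d.design_id: d for d in model.directs}
    for did, dsl in model.design_slices.items():
        r = resid[dsl]
        Vd = direct_by_id[did].V_dir
        c = float(r @ np.linalg.solve(Vd, r))
        components[did] = 0.0 if c < _ZERO_TOL else c

    n_d = net.design(design_id).n_treatments
    df = max(q_dof(net).df_inc - (n_d - 1), 0)
    if df == 0:
        q = 0.0 if q < _ZERO_TOL else q
    return DetachResult(
        design_id=design_id,
        theta_net=theta[:T],
        theta_dir_ind=theta[T:],
        residuals=resid,
        Q_inc_detached=q,
        df=df,
        p=chi2_pvalue(q, df),
        residual_components=components,
    )


def _row_components(model: AggregatedModel, resid: np.ndarray) -> np.ndarray:
    """Per-contrast-row split of the per-design quadratic forms.

    Row i of design d' contributes r_i * (V_{d'}^-1 r)_i; for two-arm
    designs this is the squared Pearson residual, and rows of a multi-arm
    design sum to its quadratic-form summand.
    """
    direct_by_id = {d.design_id: d for d in model.directs}
    out = np.zeros(model.n_rows)
    for did, sl in model.design_slices.items():
        r = resid[sl]
        out[sl] = r * np.linalg.solve(direct_by_id[did].V_dir, r)
    return out


def q_diff_matrix(model: AggregatedModel, decomp: QDecomposition) -> QDiffMatrix:
    """The matrix Q^diff_{d',d} over detachable designs.

    One column per detachable design d (detach, recompute the summands,
    subtract); one row per design-contrast of the detachable designs.
    The diagonal block of column d equals d's summand(s) before
    detaching, since d's residuals vanish in the detached model.
    """
    net = model.net
    detachable = detachable_designs(net)
    if not detachable:
        raise ValueError("net heat plot undefined (no loops)")

    resid_full = model.theta_dir_stacked - fitted_of(model)
    base_rows = _row_components(model, resid_full)

    keep_rows = np.concatenate(
        [np.arange(model.design_slices[d].start, model.design_slices[d].stop) for d in detachable]
    )
    row_labels = [model.row_labels[i] for i in keep_rows]

    cols = {}
    for d in detachable:
        _, resid_d, _ = _detached_residuals(model, d)
        cols[d] = (base_rows - _row_components(model, resid_d))[keep_rows]
    values = pd.DataFrame(cols, index=row_labels)[detachable]

    design_rows = {
        d: [model.row_labels[i]
            for i in range(model.design_slices[d].start, model.design_slices[d].stop)]
        for d in detachable
    }
    diagonal = {d: decomp.per_design_inc[d] for d in detachable}
    return QDiffMatrix(values=values, diagonal=diagonal, design_rows=design_rows)


def fitted_of(model: AggregatedModel) -> np.ndarray:
    """Consistency-model fitted values for the aggregated data."""
    from .gls import fit_network

    return fit_network(model).fitted
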