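"""Second stage: GLS fit of the consistency model and the hat matrix.

The pooled direct estimates are stacked into theta_dir and regressed on
the aggregated design matrix X_a whose T columns are the basic
parameters, the contrasts of every non-reference treatment against the
network reference A_0:

    theta_net = (X_a' V_a^-1 X_a)^-1 X_a' V_a^-1 theta_dir.

The hat matrix H = X_a (X_a' V_a^-1 X_a)^-1 X_a' V_a^-1 maps direct
estimates to fitted network estimates; row d' gives the linear
coefficients ("contributions") of every direct estimate in the network
estimate of d'.  Its diagonal is the weight of direct relative to
indirect evidence; its trace equals T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .data import DesignGroup, NetworkData

__all__ = [
    "AggregatedModel",
    "NetworkFit",
    "build_design_matrix",
    "fit_network",
    "hat_contributions",
    "study_contribution_split",
]


@dataclass(frozen=True)
class AggregatedModel:
    """Design-level regression data: X_a, stacked theta_dir, block V_a."""

    net: NetworkData
    X_a: np.ndarray
    theta_dir_stacked: np.ndarray
    V_a: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    design_slices: dict[str, slice] = field(repr=False, default_factory=dict)
    directs: tuple = ()

    @property
    def n_rows(self) -> int:
        return self.X_a.shape[0]

    def row_designs(self) -> list[str]:
        """design_id of every row of X_a."""
        out = [None] * self.n_rows
        for did, sl in self.design_slices.items():
            for i in range(sl.start, sl.stop):
                out[i] = did
        return out


@dataclass(frozen=True)
class NetworkFit:
    """GLS estimates, covariance and hat matrix of the consistency model."""

    model: AggregatedModel
    theta_net: np.ndarray
    cov_net: np.ndarray
    H: np.ndarray
    fitted: np.ndarray

    @property
    def se_net(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_net))


def build_design_matrix(net: NetworkData, directs=None) -> AggregatedModel:
    """Build the aggregated model (5): one row per design-contrast.

    Each row has +1 in the column of the contrast's non-reference
    treatment and -1 in the column of the design reference (no entry if
    the design reference is the network reference A_0).  Columns follow
    the sorted treatment order, excluding A_0.
    """
    from .pooling import pool_design

    if directs is None:
        directs = tuple(pool_design(d) for d in net.designs)
    direct_by_id = {d.design_id: d for d in directs}

    cols = {t: j for j, t in enumerate(net.treatments[1:])}
    T = len(cols)
    rows, labels, slices = [], [], {}
    y_parts, v_blocks = [], []
    pos = 0
    for group in net.designs:
        est = direct_by_id[group.design_id]
        m = group.n_treatments - 1
        slices[group.design_id] = slice(pos, pos + m)
        pos += m
        for ref, t in group.contrasts:
            row = np.zeros(T)
            row[cols[t]] = 1.0
            if ref != net.reference:
                row[cols[ref]] = -1.0
            rows.append(row)
        labels.extend(group.contrast_labels)
        y_parts.append(est.theta_dir)
        v_blocks.append(est.V_dir)

    X_a = np.vstack(rows)
    if np.linalg.matrix_rank(X_a) < T:
        raise np.linalg.LinAlgError(
            "aggregated design matrix is rank deficient; network not estimable"
        )
    return AggregatedModel(
        net=net,
        X_a=X_a,
        theta_dir_stacked=np.concatenate(y_parts),
        V_a=scipy.linalg.block_diag(*v_blocks),
        row_labels=tuple(labels),
        col_labels=tuple(net.treatments[1:]),
        design_slices=slices,
        directs=tuple(directs),
    )


def fit_network(model: AggregatedModel) -> NetworkFit:
    """Aitken (GLS) fit of the consistency model with hat matrix."""
    X, V, y = model.X_a, model.V_a, model.theta_dir_stacked
    Vinv = np.linalg.solve(V, np.eye(V.shape[0]))
    Vinv = (Vinv + Vinv.T) / 2.0
    A = X.T @ Vinv @ X
    A = (A + A.T) / 2.0
    theta = np.linalg.solve(A, X.T @ Vinv @ y)
    cov = np.linalg.solve(A, np.eye(A.shape[0]))
    cov = (cov + cov.T) / 2.0
    H = X @ np.linalg.solve(A, X.T @ Vinv)
    return NetworkFit(model=model, theta_net=theta, cov_net=cov, H=H, fitted=X @ theta)


def hat_contributions(fit: NetworkFit, percent: bool = False) -> pd.DataFrame:
    """The hat matrix with design-contrast labels.

    Row d' holds the linear coefficients of all direct estimates in the
    network estimate of d'.  With ``percent=True`` entries are rounded to
    integer percent (half away from zero) for display; raw values are
    kept otherwise.
    """
    labels = list(fit.model.row_labels)
    df = pd.DataFrame(fit.H, index=labels, columns=labels)
    if percent:
        return (np.sign(df) * np.floor(np.abs(df) * 100 + 0.5)).astype(int)
    return df


def study_contribution_split(fit: NetworkFit, design: DesignGroup) -> dict[str, float]:
    """Split a two-arm design's hat diagonal across its studies.

    The design's self-contribution h is divided proportionally to the
    studies' inverse variances, so the shares sum to h.  Not defined for
    multi-arm designs.
    """
    if design.n_treatments != 2:
        raise ValueError(
            f"study-level split unsupported for multi-arm design {design.design_id}"
        )
    sl = fit.model.design_slices[design.design_id]
    h = float(fit.H[sl.start, sl.start])
    inv_vars = np.array([1.0 / s.cov[0, 0] for s in design.studies])
    shares = inv_vars / inv_vars.sum()
    return {s.study_id: h * w for s, w in zip(design.studies, shares)}
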