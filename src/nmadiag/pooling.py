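"""First stage of the two-stage model: per-design inverse-variance pooling.

All studies of one design are summarized into a direct estimate

    theta_dir = (sum_s V_s^-1)^-1 sum_s V_s^-1 Y_s,
    V_dir     = (sum_s V_s^-1)^-1,

the multivariate inverse-variance-weighted mean.  The within-design
heterogeneity statistic Q_d^het is the generalized Cochran's Q of that
pooled fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DesignGroup
from .qstats import chi2_pvalue

__all__ = ["DirectEstimate", "DesignHeterogeneity", "pool_design", "q_het_design"]


def _symmetrize(a: np.ndarray) -> np.ndarray:
    return (a + a.T) / 2.0


@dataclass(frozen=True)
class DirectEstimate:
    """Pooled direct evidence of one design: theta_dir with covariance V_dir."""

    design_id: str
    theta_dir: np.ndarray
    V_dir: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "theta_dir", np.atleast_1d(np.asarray(self.theta_dir, float)))
        object.__setattr__(self, "V_dir", np.atleast_2d(np.asarray(self.V_dir, float)))


@dataclass(frozen=True)
class DesignHeterogeneity:
    """Q_d^het with its degrees of freedom and chi-squared p-value."""

    design_id: str
    Q: float
    df: int
    p: float


def pool_design(group: DesignGroup) -> DirectEstimate:
    """Pool all studies of a design by (multivariate) inverse variance.

    For a single-study design this returns the study's values unchanged.
    Inverses go through linear solves; accumulated matrices are
    re-symmetrized to guard against round-off drift.
    """
    first = group.studies[0]
    if len(group.studies) == 1:
        return DirectEstimate(group.design_id, first.y.copy(), first.cov.copy())
    m = len(first.y)
    W = np.zeros((m, m))
    wy = np.zeros(m)
    for s in group.studies:
        Vinv = np.linalg.solve(s.cov, np.eye(m))
        W += Vinv
        wy += Vinv @ s.y
    W = _symmetrize(W)
    try:
        theta = np.linalg.solve(W, wy)
        V_dir = _symmetrize(np.linalg.solve(W, np.eye(m)))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - PD blocks sum PD
        raise np.linalg.LinAlgError(
            f"design {group.design_id}: singular pooled precision"
        ) from exc
    return DirectEstimate(group.design_id, theta, V_dir)


def q_het_design(group: DesignGroup, direct: DirectEstimate) -> DesignHeterogeneity:
    """Within-design heterogeneity Q_d^het.

    Q_d^het = sum_{s in S_d} (Y_s - theta_dir)' V_s^-1 (Y_s - theta_dir),
    on df = sum_{s in S_d}(N_s - 1) - N_d + 1 (zero for single-study
    designs, where p is reported as 1).
    """
    q = 0.0
    for s in group.studies:
        r = s.y - direct.theta_dir
        q += float(r @ np.linalg.solve(s.cov, r))
    q = max(q, 0.0)
    df = sum(s.n_arms - 1 for s in group.studies) - group.n_treatments + 1
    return DesignHeterogeneity(group.design_id, q, df, chi2_pvalue(q, df))
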