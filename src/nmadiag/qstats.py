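"""Cochran's Q for the network and its heterogeneity/inconsistency split.

The generalized Cochran statistic of the study-level fixed-effects fit,

    Q_net = (Y - X theta_net)' V^-1 (Y - X theta_net),

decomposes exactly as Q_net = Q_het + Q_inc: a sum of within-design
heterogeneity statistics plus a between-designs inconsistency statistic

    Q_inc = (theta_dir - X_a theta_net)' V_a^-1 (theta_dir - X_a theta_net),

each approximately chi-squared under the joint null of homogeneity and
consistency.  Degrees of freedom:

    df_net = sum_s (N_s - 1) - T
    df_het = sum_d [ sum_{s in d}(N_s - 1) - N_d + 1 ]
    df_inc = sum_d (N_d - 1) - T

df_inc = 0 means the network has no loops and inconsistency is
unassessable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "QDegreesOfFreedom",
    "QDecomposition",
    "chi2_pvalue",
    "q_dof",
    "decompose_q",
]


def chi2_pvalue(Q: float, df: int) -> float:
    """Upper-tail chi-squared probability; df = 0 returns 1 by convention."""
    if Q < 0:
        raise ValueError(f"negative Q statistic: {Q}")
    if df < 0:
        raise ValueError(f"negative degrees of freedom: {df}")
    if df == 0:
        return 1.0
    return float(stats.chi2.sf(Q, df))


@dataclass(frozen=True)
class QDegreesOfFreedom:
    df_net: int
    df_het: int
    df_inc: int
    per_design_het: dict[str, int]


def q_dof(net) -> QDegreesOfFreedom:
    """All degrees of freedom, from the design-size inventory alone."""
    T = net.n_basic_parameters
    df_net = sum(s.n_arms - 1 for s in net.studies) - T
    per = {
        d.design_id: sum(s.n_arms - 1 for s in d.studies) - d.n_treatments + 1
        for d in net.designs
    }
    df_het = sum(per.values())
    df_inc = sum(d.n_treatments - 1 for d in net.designs) - T
    return QDegreesOfFreedom(df_net, df_het, df_inc, per)


@dataclass(frozen=True)
class QDecomposition:
    """Q_net = Q_het + Q_inc with per-design detail."""

    Q_net: float
    Q_het: float
    Q_inc: float
    df_net: int
    df_het: int
    df_inc: int
    p_net: float
    p_het: float
    p_inc: float
    per_design_het: dict[str, tuple[float, int, float]] = field(default_factory=dict)
    per_design_inc: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "Q_net": {"Q": self.Q_net, "df": self.df_net, "p": self.p_net},
            "Q_het": {"Q": self.Q_het, "df": self.df_het, "p": self.p_het},
            "Q_inc": {"Q": self.Q_inc, "df": self.df_inc, "p": self.p_inc},
            "per_design_het": {
                d: {"Q": q, "df": df, "p": p}
                for d, (q, df, p) in self.per_design_het.items()
            },
            "per_design_inc": dict(self.per_design_inc),
        }


def decompose_q(net, fit, directs) -> QDecomposition:
    """Decompose the network Cochran's Q into heterogeneity + inconsistency.

    Parameters
    ----------
    net
        The :class:`~nmadiag.data.NetworkData` the fit was computed from.
    fit
        A :class:`~nmadiag.gls.NetworkFit` of the aggregated model.
    directs
        The per-design :class:`~nmadiag.pooling.DirectEstimate` list used
        to build the aggregated model (same order as ``net.designs``).
    """
    from .pooling import q_het_design  # local import avoids a cycle

    dof = q_dof(net)
    direct_by_id = {d.design_id: d for d in directs}

    q_het_total = 0.0
    per_het: dict[str, tuple[float, int, float]] = {}
    for group in net.designs:
        het = q_het_design(group, direct_by_id[group.design_id])
        per_het[group.design_id] = (het.Q, het.df, het.p)
        q_het_total += het.Q

    # Q_inc: quadratic form of aggregate residuals, one summand per design
    per_inc: dict[str, float] = {}
    q_inc = 0.0
    resid = fit.model.theta_dir_stacked - fit.fitted
    for group in net.designs:
        sl = fit.model.design_slices[group.design_id]
        r = resid[sl]
        Vd = direct_by_id[group.design_id].V_dir
        q_d = float(r @ np.linalg.solve(Vd, r))
        q_d = max(q_d, 0.0)
        per_inc[group.design_id] = q_d
        q_inc += q_d

    # Q_net: study-level residuals against the network fit
    q_net = 0.0
    for group in net.designs:
        sl = fit.model.design_slices[group.design_id]
        fitted_d = fit.fitted[sl]
        for s in group.studies:
            r = s.y - fitted_d
            q_net += float(r @ np.linalg.solve(s.cov, r))

    if dof.df_inc == 0:
        warnings.warn(
            "inconsistency unassessable (no loops): df_inc = 0", stacklevel=2
        )

    return QDecomposition(
        Q_net=q_net,
        Q_het=q_het_total,
        Q_inc=q_inc,
        df_net=dof.df_net,
        df_het=dof.df_het,
        df_inc=dof.df_inc,
        p_net=chi2_pvalue(q_net, dof.df_net),
        p_het=chi2_pvalue(q_het_total, dof.df_het),
        p_inc=chi2_pvalue(q_inc, dof.df_inc),
        per_design_het=per_het,
        per_design_inc=per_inc,
    )
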