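"""Contrast-level input handling for network meta-analysis.

A network meta-analysis combines studies that each report relative
treatment effects (e.g. log odds ratios or mean differences) for a set of
treatments.  Studies comparing exactly the same treatment set form a
*design*; designs are the unit at which inconsistency between direct and
indirect evidence can be assessed.

Input is a contrast table with columns ``study, treat1, treat2, effect,
se`` where ``effect`` is the effect of ``treat2`` relative to ``treat1``.
Multi-arm studies report correlated contrasts; their covariance block is
assembled from arm-level variances (``Var(Y_0i) = v_0 + v_i``,
``Cov(Y_0i, Y_0j) = v_0``) supplied in a sidecar table, or recovered from
the full set of pairwise standard errors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "StudyRecord",
    "DesignGroup",
    "NetworkData",
    "NetworkFormatError",
    "DisconnectedNetworkError",
    "UnderspecifiedCovarianceError",
    "parse_contrast_table",
    "read_contrast_table",
    "to_contrast_table",
    "design_graph",
    "design_id_for",
]

_SYM_TOL = 1e-10


class NetworkFormatError(ValueError):
    """Malformed contrast table (duplicates, bad treatment sets, bad SEs)."""


class DisconnectedNetworkError(ValueError):
    """The treatment graph is not connected."""

    def __init__(self, components):
        self.components = [sorted(c) for c in components]
        parts = "; ".join("{" + ", ".join(c) + "}" for c in self.components)
        super().__init__(f"treatment network is disconnected: components {parts}")


class UnderspecifiedCovarianceError(ValueError):
    """A multi-arm study's covariance block cannot be derived from the input."""


def design_id_for(treatments) -> str:
    """Canonical design label: sorted treatment names joined by ':'."""
    return ":".join(sorted(treatments))


@dataclass(frozen=True)
class StudyRecord:
    """One study's contrast observations against its design reference.

    ``y[k]`` is the effect of ``treatments[k+1]`` relative to ``reference``
    (the lexicographically smallest treatment), and ``cov`` is the
    corresponding sampling covariance block, assumed known.
    """

    study_id: str
    treatments: tuple[str, ...]
    reference: str
    y: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "treatments", tuple(sorted(self.treatments)))
        y = np.atleast_1d(np.asarray(self.y, dtype=float))
        cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "cov", cov)
        if self.reference not in self.treatments:
            raise NetworkFormatError(
                f"study {self.study_id}: reference {self.reference!r} not among "
                f"treatments {self.treatments}"
            )
        m = len(self.treatments) - 1
        if y.shape != (m,) or cov.shape != (m, m):
            raise NetworkFormatError(
                f"study {self.study_id}: expected {m} contrasts, got y{y.shape} "
                f"cov{cov.shape}"
            )
        if not np.allclose(cov, cov.T, atol=_SYM_TOL):
            raise NetworkFormatError(f"study {self.study_id}: covariance not symmetric")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise NetworkFormatError(
                f"study {self.study_id}: covariance not positive definite"
            )

    @property
    def n_arms(self) -> int:
        return len(self.treatments)

    @property
    def design_id(self) -> str:
        return design_id_for(self.treatments)

    @property
    def contrasts(self) -> list[tuple[str, str]]:
        """(reference, treatment) pairs in the order of ``y``."""
        return [(self.reference, t) for t in self.treatments if t != self.reference]


@dataclass(frozen=True)
class DesignGroup:
    """All studies sharing one treatment set (a component meta-analysis)."""

    design_id: str
    treatments: tuple[str, ...]
    reference: str
    studies: tuple[StudyRecord, ...]

    def __post_init__(self):
        object.__setattr__(self, "treatments", tuple(sorted(self.treatments)))
        object.__setattr__(self, "studies", tuple(self.studies))
        for s in self.studies:
            if s.treatments != self.treatments:
                raise NetworkFormatError(
                    f"study {s.study_id} does not match design {self.design_id}"
                )
            if s.reference != self.reference:
                raise NetworkFormatError(
                    f"study {s.study_id}: reference differs from design reference"
                )

    @property
    def n_treatments(self) -> int:
        return len(self.treatments)

    @property
    def contrasts(self) -> list[tuple[str, str]]:
        return [(self.reference, t) for t in self.treatments if t != self.reference]

    @property
    def contrast_labels(self) -> list[str]:
        """Row labels such as ``'1:2'``; multi-arm contrasts carry a '*'."""
        if self.n_treatments == 2:
            return [self.design_id]
        return [f"{a}:{b}*" for a, b in self.contrasts]


@dataclass(frozen=True)
class NetworkData:
    """A connected network of designs; the input to the two-stage model."""

    treatments: tuple[str, ...]
    designs: tuple[DesignGroup, ...]
    studies: tuple[StudyRecord, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "treatments", tuple(sorted(self.treatments)))
        designs = tuple(sorted(self.designs, key=lambda d: d.design_id))
        object.__setattr__(self, "designs", designs)
        if self.studies is None:
            object.__setattr__(
                self, "studies", tuple(s for d in designs for s in d.studies)
            )
        g = design_graph(self)
        missing = set(self.treatments) - set(g.nodes)
        if missing:
            raise NetworkFormatError(f"treatments never compared: {sorted(missing)}")
        if g.number_of_nodes() and not nx.is_connected(g):
            raise DisconnectedNetworkError(nx.connected_components(g))

    @property
    def reference(self) -> str:
        """Network reference treatment A_0 (lexicographically smallest)."""
        return self.treatments[0]

    @property
    def n_treatments(self) -> int:
        return len(self.treatments)

    @property
    def n_basic_parameters(self) -> int:
        """T: contrasts of each non-reference treatment versus A_0."""
        return len(self.treatments) - 1

    @property
    def n_designs(self) -> int:
        return len(self.designs)

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    def design(self, design_id: str) -> DesignGroup:
        for d in self.designs:
            if d.design_id == design_id:
                return d
        raise KeyError(design_id)


def design_graph(net: NetworkData) -> nx.MultiGraph:
    """Treatment graph: one edge per within-design pair, tagged by design."""
    g = nx.MultiGraph()
    for d in net.designs:
        for a, b in itertools.combinations(d.treatments, 2):
            g.add_edge(a, b, design=d.design_id)
    for t in net.treatments:
        g.add_node(t)
    return g


def _solve_arm_variances(treatments, pair_se2):
    """Recover arm variances v_i from pairwise variances se2(i,j) = v_i + v_j."""
    idx = {t: i for i, t in enumerate(treatments)}
    rows, b = [], []
    for (a, c), v in pair_se2.items():
        r = np.zeros(len(treatments))
        r[idx[a]] = 1.0
        r[idx[c]] = 1.0
        rows.append(r)
        b.append(v)
    A = np.asarray(rows)
    sol, *_ = np.linalg.lstsq(A, np.asarray(b), rcond=None)
    return {t: sol[idx[t]] for t in treatments}


def _block_from_arm_variances(treatments, reference, arm_var):
    """Compound-symmetric block: Var(Y_0i)=v_0+v_i, Cov(Y_0i,Y_0j)=v_0."""
    non_ref = [t for t in treatments if t != reference]
    m = len(non_ref)
    v0 = arm_var[reference]
    cov = np.full((m, m), v0)
    for k, t in enumerate(non_ref):
        cov[k, k] = v0 + arm_var[t]
    return cov


def parse_contrast_table(
    rows: pd.DataFrame, arm_variances: pd.DataFrame | None = None
) -> NetworkData:
    """Assemble a :class:`NetworkData` from a contrast table.

    Parameters
    ----------
    rows
        Columns ``study, treat1, treat2, effect, se``; ``effect`` is
        treat2 minus treat1 on the chosen effect scale.
    arm_variances
        Optional table with columns ``study, treatment, var`` giving
        arm-level variances for multi-arm studies.

    Contrasts are re-oriented to each design's reference (the smallest
    treatment label); all downstream Q statistics are invariant to that
    choice, so a canonical orientation loses nothing.
    """
    required = {"study", "treat1", "treat2", "effect", "se"}
    if not required.issubset(rows.columns):
        raise NetworkFormatError(
            f"missing columns: {sorted(required - set(rows.columns))}"
        )
    rows = rows.astype({"study": str, "treat1": str, "treat2": str})
    if (rows["se"] <= 0).any():
        bad = rows.loc[rows["se"] <= 0, "study"].tolist()
        raise NetworkFormatError(f"non-positive standard errors in studies {bad}")

    arm_var_by_study: dict[str, dict[str, float]] = {}
    if arm_variances is not None:
        av = arm_variances.astype({"study": str, "treatment": str})
        for (sid,), grp in av.groupby(["study"]):
            arm_var_by_study[sid] = dict(
                zip(grp["treatment"], grp["var"].astype(float))
            )

    records: list[StudyRecord] = []
    for sid, grp in rows.groupby("study", sort=True):
        pair_seen = set()
        effects: dict[tuple[str, str], float] = {}
        pair_se2: dict[tuple[str, str], float] = {}
        for _, r in grp.iterrows():
            a, b = r["treat1"], r["treat2"]
            if a == b:
                raise NetworkFormatError(f"study {sid}: self-comparison {a}:{b}")
            key = tuple(sorted((a, b)))
            if key in pair_seen:
                raise NetworkFormatError(
                    f"study {sid}: duplicate rows for pair {key[0]}:{key[1]}"
                )
            pair_seen.add(key)
            # orient as (smaller, larger): effect of larger vs smaller
            eff = float(r["effect"]) if key == (a, b) else -float(r["effect"])
            effects[key] = eff
            pair_se2[key] = float(r["se"]) ** 2

        treatments = sorted({t for p in pair_seen for t in p})
        ref = treatments[0]
        n = len(treatments)
        non_ref = treatments[1:]

        if n == 2:
            y = np.array([effects[(ref, non_ref[0])]])
            cov = np.array([[pair_se2[(ref, non_ref[0])]]])
        else:
            missing_ref_pairs = [t for t in non_ref if (ref, t) not in effects]
            if missing_ref_pairs:
                raise NetworkFormatError(
                    f"study {sid}: inconsistent treatment set — no contrast of "
                    f"{missing_ref_pairs} against {ref}"
                )
            y = np.array([effects[(ref, t)] for t in non_ref])
            if sid in arm_var_by_study:
                av = arm_var_by_study[sid]
                missing = [t for t in treatments if t not in av]
                if missing:
                    raise UnderspecifiedCovarianceError(
                        f"study {sid}: arm variances missing for {missing}"
                    )
            elif len(pair_seen) == n * (n - 1) // 2:
                av = _solve_arm_variances(treatments, pair_se2)
                if any(v <= 0 for v in av.values()):
                    raise UnderspecifiedCovarianceError(
                        f"study {sid}: pairwise SEs imply non-positive arm "
                        f"variances {av}"
                    )
            else:
                raise UnderspecifiedCovarianceError(
                    f"study {sid}: multi-arm study needs arm variances or all "
                    f"{n * (n - 1) // 2} pairwise standard errors"
                )
            cov = _block_from_arm_variances(treatments, ref, av)

        records.append(StudyRecord(str(sid), tuple(treatments), ref, y, cov))

    groups: dict[str, list[StudyRecord]] = {}
    for rec in records:
        groups.setdefault(rec.design_id, []).append(rec)
    designs = tuple(
        DesignGroup(did, recs[0].treatments, recs[0].reference, tuple(recs))
        for did, recs in sorted(groups.items())
    )
    treatments = sorted({t for rec in records for t in rec.treatments})
    return NetworkData(tuple(treatments), designs)


def read_contrast_table(
    path, arm_vars_path=None, sep: str | None = None
) -> NetworkData:
    """Read a CSV/TSV contrast table (auto-detected delimiter by default)."""
    rows = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    arm = pd.read_csv(arm_vars_path) if arm_vars_path is not None else None
    return parse_contrast_table(rows, arm)


def to_contrast_table(net: NetworkData) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Serialize back to (contrast table, arm-variance table or None).

    Multi-arm covariance blocks must be of the compound-symmetric form
    produced by arm variances; anything else cannot be represented in the
    two-table format and raises ``ValueError``.
    """
    rows = []
    arm_rows = []
    for s in net.studies:
        if s.n_arms == 2:
            a, b = s.contrasts[0]
            rows.append((s.study_id, a, b, s.y[0], float(np.sqrt(s.cov[0, 0]))))
            continue
        off = s.cov[~np.eye(s.cov.shape[0], dtype=bool)]
        v0 = float(off[0])
        if not np.allclose(off, v0, atol=1e-9) or v0 <= 0:
            raise ValueError(
                f"study {s.study_id}: covariance block is not representable by "
                "arm-level variances"
            )
        arm_rows.append((s.study_id, s.reference, v0))
        for k, (a, b) in enumerate(s.contrasts):
            vb = float(s.cov[k, k] - v0)
            arm_rows.append((s.study_id, b, vb))
            rows.append((s.study_id, a, b, s.y[k], float(np.sqrt(s.cov[k, k]))))
    table = pd.DataFrame(rows, columns=["study", "treat1", "treat2", "effect", "se"])
    arm = (
        pd.DataFrame(arm_rows, columns=["study", "treatment", "var"])
        if arm_rows
        else None
    )
    return table, arm
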