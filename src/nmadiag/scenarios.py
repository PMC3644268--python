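"""Synthetic networks: the illustrative six-treatment examples and simulators.

The illustrative networks use six treatments labelled "1".."6", one
single-study design per edge with unit variance, and all effects zero
except a perturbation delta (default 5, i.e. five standard errors of a
direct estimate) on one chosen design.  Three topologies appear:

* ``fig1_a`` / ``fig3_b`` / ``fig3_c`` — the 8-edge network
  {1:2, 1:3, 1:6, 2:3, 3:4, 4:5, 4:6, 5:6} (two triangles joined by two
  bridging edges that each lie on a cycle);
* ``fig3_d`` — the single 6-cycle 1:2, 2:3, 3:4, 4:5, 5:6, 1:6;
* ``fig3_e`` — the complete graph on six treatments (15 designs).

``simulate_network`` draws study effects around a consistent truth for
null-distribution and recovery testing; ``diabetes_structure`` rebuilds
the design-size inventory (study counts, design sizes) of a published
ten-treatment glucose-lowering network as a synthetic structure-only
dataset for degrees-of-freedom bookkeeping.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data import DesignGroup, NetworkData, StudyRecord, design_id_for

__all__ = [
    "ScenarioSpec",
    "SCENARIO_EDGES",
    "make_scenario",
    "simulate_network",
    "random_topology",
    "diabetes_structure",
]

_EIGHT_EDGES = (
    ("1", "2"), ("1", "3"), ("1", "6"), ("2", "3"),
    ("3", "4"), ("4", "5"), ("4", "6"), ("5", "6"),
)
_CYCLE_EDGES = (("1", "2"), ("2", "3"), ("3", "4"), ("4", "5"), ("5", "6"), ("1", "6"))

SCENARIO_EDGES: dict[str, tuple[tuple[str, str], ...]] = {
    "fig1_a": _EIGHT_EDGES,
    "fig3_b": _EIGHT_EDGES,
    "fig3_c": _EIGHT_EDGES,
    "fig3_d": _CYCLE_EDGES,
    "fig3_e": tuple(itertools.combinations("123456", 2)),
    "triangle": (("1", "2"), ("1", "3"), ("2", "3")),
}

# the perturbed design conventionally shown for each scenario
DEFAULT_PERTURBED = {
    "fig1_a": "1:2",
    "fig3_b": "1:6",
    "fig3_c": "1:3",
    "fig3_d": "1:2",
    "fig3_e": "1:2",
    "triangle": "1:2",
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Which illustrative network to build and where to perturb it."""

    name: str = "fig1_a"
    perturbed_design: str | None = None
    delta: float = 5.0
    seed: int | None = None  # used by name="random"

    def resolved_perturbed(self) -> str:
        return (
            self.perturbed_design
            if self.perturbed_design is not None
            else DEFAULT_PERTURBED.get(self.name, "")
        )


def _edges_to_network(edges, effects: dict[str, float]) -> NetworkData:
    designs = []
    for a, b in edges:
        did = design_id_for((a, b))
        y = np.array([effects.get(did, 0.0)])
        rec = StudyRecord(f"study_{did}", (a, b), min(a, b), y, np.array([[1.0]]))
        designs.append(DesignGroup(did, rec.treatments, rec.reference, (rec,)))
    treatments = sorted({t for e in edges for t in e})
    return NetworkData(tuple(treatments), tuple(designs))


def make_scenario(spec: ScenarioSpec) -> NetworkData:
    """Build an illustrative network: unit variances, one study per design.

    All effects are zero except ``delta`` on the perturbed design, so any
    nonzero Q is pure inconsistency (single-study designs cannot be
    heterogeneous).
    """
    if spec.name == "random":
        edges = random_topology(np.random.default_rng(spec.seed))
    elif spec.name in SCENARIO_EDGES:
        edges = SCENARIO_EDGES[spec.name]
    else:
        raise ValueError(
            f"unknown scenario {spec.name!r}; choose from "
            f"{sorted(SCENARIO_EDGES) + ['random']}"
        )
    perturbed = spec.resolved_perturbed()
    edge_ids = {design_id_for(e) for e in edges}
    if perturbed and perturbed not in edge_ids:
        raise ValueError(f"design {perturbed!r} not in scenario {spec.name}")
    if not np.isfinite(spec.delta):
        raise ValueError("delta must be finite")
    return _edges_to_network(edges, {perturbed: spec.delta} if perturbed else {})


def random_topology(rng: np.random.Generator, n_treatments: int = 6, extra_edges: int = 3):
    """A random connected two-arm topology: spanning tree plus extra edges."""
    labels = [str(i + 1) for i in range(n_treatments)]
    order = list(rng.permutation(labels))
    edges = set()
    for i, t in enumerate(order[1:], start=1):
        anchor = order[int(rng.integers(0, i))]
        edges.add(tuple(sorted((anchor, t))))
    candidates = [
        e for e in itertools.combinations(labels, 2) if tuple(sorted(e)) not in edges
    ]
    rng.shuffle(candidates)
    for e in candidates[:extra_edges]:
        edges.add(tuple(sorted(e)))
    return tuple(sorted(edges))


def simulate_network(
    topology,
    theta: dict[str, float] | None = None,
    het_sd: float = 0.0,
    n_studies_per_design: int = 1,
    seed: int | None = None,
    variance: float = 1.0,
) -> NetworkData:
    """Simulate study-level data around a consistent truth.

    Parameters
    ----------
    topology
        Iterable of treatment pairs (two-arm designs).
    theta
        Basic parameters: effect of each treatment versus the smallest
        label (missing entries are 0); design truths follow by
        consistency.
    het_sd
        Between-study standard deviation of a per-study effect shift
        (0 = homogeneous).
    n_studies_per_design, seed, variance
        Study count per design, RNG seed, sampling variance per study.
    """
    if het_sd < 0:
        raise ValueError("het_sd must be non-negative")
    edges = [tuple(sorted(e)) for e in topology]
    g = nx.Graph(edges)
    if g.number_of_nodes() and not nx.is_connected(g):
        raise ValueError("topology is not connected")
    rng = np.random.default_rng(seed)
    theta = theta or {}
    ref = sorted(g.nodes)[0]

    def basic(t: str) -> float:
        return 0.0 if t == ref else float(theta.get(t, 0.0))

    designs = []
    for a, b in sorted(edges):
        did = design_id_for((a, b))
        true_effect = basic(b) - basic(a)
        recs = []
        for k in range(n_studies_per_design):
            mu = true_effect + (rng.normal(0.0, het_sd) if het_sd > 0 else 0.0)
            yk = rng.normal(mu, np.sqrt(variance))
            recs.append(
                StudyRecord(
                    f"{did}_s{k + 1}", (a, b), a, np.array([yk]),
                    np.array([[variance]]),
                )
            )
        designs.append(DesignGroup(did, recs[0].treatments, a, tuple(recs)))
    treatments = sorted(g.nodes)
    return NetworkData(tuple(treatments), tuple(designs))


def diabetes_structure() -> NetworkData:
    """Synthetic structure-only replica of a ten-treatment diabetes network.

    Reproduces only the design-size inventory (15 designs, 26 studies,
    one three-arm design) needed for degrees-of-freedom bookkeeping; all
    effects are zero and all variances one — the real outcome data are
    not included.
    """
    two_arm = {
        "acar:plac": 1, "benf:plac": 2, "metf:plac": 3, "migl:plac": 3,
        "piog:plac": 1, "plac:rosi": 6, "plac:sita": 1, "plac:vild": 1,
        "acar:SUal": 1, "metf:piog": 1, "metf:rosi": 2, "metf:SUal": 1,
        "piog:rosi": 1, "rosi:SUal": 1,
    }
    designs = []
    for did, n in sorted(two_arm.items()):
        a, b = sorted(did.split(":"))
        recs = tuple(
            StudyRecord(f"{did}_s{k + 1}", (a, b), a, np.zeros(1), np.eye(1))
            for k in range(n)
        )
        designs.append(DesignGroup(design_id_for((a, b)), (a, b), a, recs))
    arms = ("acar", "metf", "plac")
    cov = np.array([[2.0, 1.0], [1.0, 2.0]])  # unit arm variances
    rec = StudyRecord("acar:metf:plac_s1", arms, "acar", np.zeros(2), cov)
    designs.append(DesignGroup(design_id_for(arms), arms, "acar", (rec,)))
    treatments = sorted({t for d in designs for t in d.treatments})
    return NetworkData(tuple(treatments), tuple(designs))
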