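"""Synthetic data with planted ground truth.

Two generators stand in for curated comparative-genomics inputs so that
every pipeline stage can be exercised, and its recovery quantified,
without any external download.

``gen_matrix`` draws integer paralog counts for organisms partitioned
into clades.  Baseline counts are Poisson (optionally negative binomial
for overdispersion); planted *expansion* events multiply the Poisson
mean of one family inside one clade, emulating a lineage-specific
duplication burst, and planted *loss* events zero that block, emulating
clade-wide gene loss.  The clade assignment, event list and seed are
returned as ground truth.

``gen_core_periphery`` builds a PPI-like graph with a dense
Erdős–Rényi core containing one planted clique, plus a sparse periphery
in which every node attaches to at least one core node — the
hub-and-core shape that produces an inverse (hyperbolic) degree
distribution rather than a power law.

A matching ultrametric-free species tree (clades as subtrees) is
provided so Dollo reconstruction can be tested against planted losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import networkx as nx
import numpy as np

from .ancestral import SpeciesTree
from .phyletic import CladeAnnotation, ParalogCountMatrix

EventKind = Literal["expansion", "loss"]


@dataclass(frozen=True)
class PlantedEvent:
    """One planted (family, clade) perturbation."""

    family: str
    clade: str
    kind: EventKind
    multiplier: float = 1.0  # expansion fold change; ignored for losses

    def __post_init__(self) -> None:
        if self.kind not in ("expansion", "loss"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "expansion" and self.multiplier < 1:
            raise ValueError("expansion multiplier must be >= 1")


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Everything planted: clades, events, baseline rates, network core."""

    seed: int
    clade_of: dict[str, str] = field(default_factory=dict)
    events: tuple[PlantedEvent, ...] = ()
    baseline_rate: dict[str, float] = field(default_factory=dict)
    core_nodes: frozenset[str] = frozenset()
    planted_clique: frozenset[str] = frozenset()


def _partition(n: int, k: int) -> list[int]:
    """Split n items into k near-equal groups."""
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def gen_matrix(
    n_organisms: int = 100,
    n_families: int = 30,
    n_clades: int = 4,
    events: Sequence[PlantedEvent] | None = None,
    baseline_rate: float = 1.0,
    seed: int = 0,
    dispersion: float | None = None,
    n_representatives: int = 3,
) -> tuple[ParalogCountMatrix, CladeAnnotation, SyntheticGroundTruth]:
    """Generate a clade-structured paralog-count matrix with ground truth.

    Counts are Poisson(baseline_rate × multiplier) per cell, where the
    multiplier is the product of all planted expansions hitting that
    (family, clade) block; loss events zero the block afterwards.  When
    ``dispersion`` (negative-binomial size parameter; smaller = more
    overdispersed) is given, counts are negative binomial with the same
    mean instead.  The first ``n_representatives`` organisms of each
    clade are marked as LDA prior-group representatives.  Deterministic
    given ``seed``.
    """
    if n_organisms < 1 or n_families < 1 or n_clades < 1:
        raise ValueError("n_organisms, n_families, n_clades must be positive")
    if n_clades > n_organisms:
        raise ValueError("more clades than organisms")
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    rng = np.random.default_rng(seed)

    clade_names = [f"clade{c + 1}" for c in range(n_clades)]
    organisms = [f"org{i + 1:03d}" for i in range(n_organisms)]
    families = [f"fam{j + 1:02d}" for j in range(n_families)]
    events = tuple(events or ())
    fam_set, clade_set = set(families), set(clade_names)
    for ev in events:
        if ev.family not in fam_set:
            raise ValueError(f"event names unknown family {ev.family!r}")
        if ev.clade not in clade_set:
            raise ValueError(f"event names unknown clade {ev.clade!r}")

    sizes = _partition(n_organisms, n_clades)
    clade_of: dict[str, str] = {}
    reps: set[str] = set()
    pos = 0
    for cname, size in zip(clade_names, sizes):
        block = organisms[pos : pos + size]
        for o in block:
            clade_of[o] = cname
        reps.update(block[: min(n_representatives, size)])
        pos += size

    # per-cell Poisson mean = baseline * product of expansion multipliers
    mean = np.full((n_organisms, n_families), float(baseline_rate))
    fam_idx = {f: j for j, f in enumerate(families)}
    clade_rows = {
        c: np.array([i for i, o in enumerate(organisms) if clade_of[o] == c])
        for c in clade_names
    }
    for ev in events:
        if ev.kind == "expansion":
            mean[np.ix_(clade_rows[ev.clade], [fam_idx[ev.family]])] *= ev.multiplier
    if dispersion is None:
        counts = rng.poisson(mean)
    else:
        if dispersion <= 0:
            raise ValueError("dispersion must be positive")
        p = dispersion / (dispersion + mean)
        counts = rng.negative_binomial(dispersion, p)
    for ev in events:
        if ev.kind == "loss":
            counts[np.ix_(clade_rows[ev.clade], [fam_idx[ev.family]])] = 0

    m = ParalogCountMatrix(organisms, families, counts)
    ca = CladeAnnotation(clade_of, frozenset(reps))
    gt = SyntheticGroundTruth(
        seed=seed,
        clade_of=dict(clade_of),
        events=events,
        baseline_rate={f: float(baseline_rate) for f in families},
    )
    return m, ca, gt


def planted_block_events(
    n_clades: int,
    n_families: int,
    multiplier: float = 5.0,
    families_per_clade: int | None = None,
) -> list[PlantedEvent]:
    """A standard design: each clade gets an expansion of its own
    contiguous block of families, giving every clade a distinct profile."""
    per = families_per_clade or max(1, n_families // n_clades)
    events = []
    for c in range(n_clades):
        for j in range(c * per, min((c + 1) * per, n_families)):
            events.append(
                PlantedEvent(f"fam{j + 1:02d}", f"clade{c + 1}", "expansion", multiplier)
            )
    return events


def clade_tree(ca: CladeAnnotation) -> SpeciesTree:
    """Rake-of-rakes species tree: one multifurcating subtree per clade.

    A deliberately coarse topology — within-clade relationships are left
    unresolved — sufficient for testing clade-level gain/loss placement.
    """
    parts = []
    for clade in ca.clade_names:
        members = sorted(ca.members(clade))
        if len(members) == 1:
            parts.append(members[0])
        else:
            parts.append("(" + ",".join(members) + ")" + clade)
    newick = "(" + ",".join(parts) + ")root;"
    return SpeciesTree.from_newick(newick)


def gen_core_periphery(
    n_core: int = 46,
    n_periphery: int = 127,
    p_core: float = 0.5,
    p_attach: float = 0.02,
    planted_clique: int = 10,
    seed: int = 0,
) -> tuple[nx.Graph, SyntheticGroundTruth]:
    """Core–periphery graph with a planted clique of known size.

    The core is Erdős–Rényi G(n_core, p_core) with a clique forced on
    its first ``planted_clique`` nodes; each periphery node gets one
    guaranteed uniform-random link to the core plus Binomial(n_core,
    p_attach) extra core links.  All edges carry class ``funcoup``
    except planted-clique edges, which are ``literature_specific``
    (the curated dense core).  Deterministic given ``seed``.
    """
    if not (0 <= p_core <= 1 and 0 <= p_attach <= 1):
        raise ValueError("probabilities must be in [0, 1]")
    if planted_clique > n_core:
        raise ValueError("planted clique larger than core")
    rng = np.random.default_rng(seed)
    core = [f"core{i + 1:03d}" for i in range(n_core)]
    peri = [f"peri{i + 1:03d}" for i in range(n_periphery)]
    g = nx.Graph()
    g.add_nodes_from(core, role="core")
    g.add_nodes_from(peri, role="periphery")
    for i in range(n_core):
        for j in range(i + 1, n_core):
            if i < planted_clique and j < planted_clique:
                g.add_edge(core[i], core[j], edge_class="literature_specific")
            elif rng.random() < p_core:
                g.add_edge(core[i], core[j], edge_class="funcoup")
    for p in peri:
        anchor = core[int(rng.integers(n_core))]
        g.add_edge(p, anchor, edge_class="funcoup")
        extra = rng.random(n_core) < p_attach
        for i in np.flatnonzero(extra):
            if core[i] != anchor:
                g.add_edge(p, core[i], edge_class="funcoup")
    gt = SyntheticGroundTruth(
        seed=seed,
        core_nodes=frozenset(core),
        planted_clique=frozenset(core[:planted_clique]),
    )
    return g, gt
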