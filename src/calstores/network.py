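"""Protein–protein interaction network assembly and dense-core extraction.

The network is a simple undirected graph of proteins with typed edges:
interactions curated from the literature with paralog-specific support
(``literature_specific``), literature interactions where the paralog is
ambiguous (``literature_ambiguous``), and high-confidence predicted
functional couplings (``funcoup``).  Duplicate input pairs collapse to
one edge, keeping the most specific class.

Two structural analyses are provided.  The degree distribution is fit
with a single-parameter rectangular hyperbola N(d) = a/d, whose quality
of fit (R²) distinguishes a hub-and-core topology from the power-law
shape typical of whole-interactome networks.  The dense core itself is
extracted by enumerating maximal cliques (Bron–Kerbosch with pivoting)
and merging all cliques of at least a threshold size into one induced
subnetwork.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("calstores")

EDGE_CLASSES = ("literature_specific", "literature_ambiguous", "funcoup")
# most specific wins when duplicate pairs disagree
_CLASS_RANK = {c: i for i, c in enumerate(EDGE_CLASSES)}

PHYLETIC_CLASSES = (
    "pan-eukaryotic",
    "metazoa+relatives",
    "metazoan-specific",
    "chordate-specific",
    "other",
)


def build_network(
    edges: Iterable[tuple[str, str, str]],
    node_attrs: dict[str, dict] | None = None,
) -> nx.Graph:
    """Assemble a simple undirected typed graph from (u, v, class) triples.

    Self-loops are dropped with a warning; duplicate pairs collapse with
    class precedence literature_specific > literature_ambiguous > funcoup.
    """
    g = nx.Graph()
    for u, v, cls in edges:
        if cls not in _CLASS_RANK:
            raise ValueError(f"unknown edge class {cls!r} on {u}-{v}")
        if u == v:
            logger.warning("dropping self-loop on %r", u)
            continue
        if g.has_edge(u, v):
            old = g.edges[u, v]["edge_class"]
            if _CLASS_RANK[cls] < _CLASS_RANK[old]:
                g.edges[u, v]["edge_class"] = cls
        else:
            g.add_edge(u, v, edge_class=cls)
    if node_attrs:
        for node, attrs in node_attrs.items():
            if node not in g:
                g.add_node(node)
            g.nodes[node].update(attrs)
    return g


def read_network(path: str | Path, node_attrs_path: str | Path | None = None) -> nx.Graph:
    """Read an edge-list TSV (columns source, target, class) and optional
    node-attribute TSV (column ``node`` plus free attribute columns)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.empty and df.columns.size == 0:
        return nx.Graph()
    cols = {c.lower(): c for c in df.columns}
    for needed in ("source", "target", "class"):
        if needed not in cols:
            raise ValueError(f"{path}: edge list needs columns source, target, class")
    triples = zip(
        df[cols["source"]].astype(str),
        df[cols["target"]].astype(str),
        df[cols["class"]].astype(str),
    )
    attrs = None
    if node_attrs_path is not None:
        adf = pd.read_csv(node_attrs_path, sep="\t", comment="#", dtype=str)
        acols = {c.lower(): c for c in adf.columns}
        if "node" not in acols:
            raise ValueError(f"{node_attrs_path}: node table needs a 'node' column")
        attrs = {
            str(row[acols["node"]]): {
                k: row[c] for k, c in acols.items() if k != "node" and pd.notna(row[c])
            }
            for _, row in adf.iterrows()
        }
    g = build_network(triples, attrs)
    logger.info("read network %s: %d nodes, %d edges", path, g.number_of_nodes(), g.number_of_edges())
    return g


def write_network(g: nx.Graph, path: str | Path) -> None:
    rows = [
        {"source": u, "target": v, "class": d.get("edge_class", "literature_specific")}
        for u, v, d in sorted(g.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "class"]).to_csv(path, sep="\t", index=False)


def filter_edge_classes(g: nx.Graph, keep: Sequence[str]) -> nx.Graph:
    """Subgraph with only edges whose class is in ``keep`` (nodes retained)."""
    keep = set(keep)
    unknown = keep - set(EDGE_CLASSES)
    if unknown:
        raise ValueError(f"unknown edge classes {sorted(unknown)}")
    h = nx.Graph()
    h.add_nodes_from(g.nodes(data=True))
    h.add_edges_from(
        (u, v, d) for u, v, d in g.edges(data=True) if d.get("edge_class") in keep
    )
    return h


# ---------------------------------------------------------------------------
# Degree distribution
# ---------------------------------------------------------------------------

def degree_histogram(g: nx.Graph) -> list[tuple[int, int]]:
    """(degree, node count) pairs over observed degrees, ascending."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph has no degree histogram")
    counts: dict[int, int] = {}
    for _, d in g.degree():
        counts[d] = counts.get(d, 0) + 1
    return sorted(counts.items())


@dataclass(frozen=True)
class DegreeFit:
    """Least-squares fit of the rectangular hyperbola N(d) = a / d."""

    a: float
    r_squared: float
    degrees: tuple[int, ...] = ()
    counts: tuple[int, ...] = ()

    def predict(self, d: np.ndarray) -> np.ndarray:
        return self.a / np.asarray(d, dtype=float)


def fit_inverse(hist: Sequence[tuple[int, int]]) -> DegreeFit:
    """Fit N(d) = a/d to a degree histogram by ordinary least squares.

    Degree-0 nodes cannot sit on a hyperbola and are excluded.  R² is
    computed on the histogram counts (1 - SS_res/SS_tot) and may be
    negative when the hyperbola fits worse than the mean.
    """
    pts = [(d, n) for d, n in hist if d >= 1]
    if len(pts) < 2:
        raise ValueError("inverse fit needs at least 2 distinct degrees >= 1")
    d = np.array([p[0] for p in pts], dtype=float)
    n = np.array([p[1] for p in pts], dtype=float)
    x = 1.0 / d
    a = float((x @ n) / (x @ x))  # closed-form OLS through the origin
    resid = n - a * x
    ss_res = float(resid @ resid)
    ss_tot = float(((n - n.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return DegreeFit(a=a, r_squared=r2, degrees=tuple(int(v) for v in d), counts=tuple(int(v) for v in n))


# ---------------------------------------------------------------------------
# Cliques and the merged dense core
# ---------------------------------------------------------------------------

def maximal_cliques(g: nx.Graph) -> list[tuple[str, ...]]:
    """All maximal cliques, each sorted, in deterministic sorted order."""
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(g)]
    return sorted(cliques)


@dataclass(frozen=True)
class CliqueSubnetwork:
    """Union of all maximal cliques of size >= ``merge_threshold``."""

    merge_threshold: int
    max_clique_size: int
    node_set: frozenset[str]
    subgraph: nx.Graph = field(repr=False, compare=False)
    edge_fraction: float = 0.0

    @property
    def n_nodes(self) -> int:
        return len(self.node_set)


def merge_cliques(g: nx.Graph, k: int) -> CliqueSubnetwork:
    """Merge all maximal cliques of size >= k into one induced subnetwork.

    ``edge_fraction`` is the share of the whole network's edges that lie
    inside the induced subgraph of the merged node set.  No qualifying
    clique yields an empty subnetwork (fraction 0), not an error.
    """
    if k < 2:
        raise ValueError("merge threshold k must be >= 2")
    cliques = maximal_cliques(g)
    max_size = max((len(c) for c in cliques), default=0)
    nodes: set[str] = set()
    for c in cliques:
        if len(c) >= k:
            nodes.update(c)
    sub = g.subgraph(nodes).copy()
    total = g.number_of_edges()
    frac = sub.number_of_edges() / total if total else 0.0
    return CliqueSubnetwork(
        merge_threshold=k,
        max_clique_size=max_size,
        node_set=frozenset(nodes),
        subgraph=sub,
        edge_fraction=frac,
    )


def network_summary(g: nx.Graph, merge_k: int = 6) -> dict:
    """Headline statistics: size, degree fit, largest clique, merged core."""
    hist = degree_histogram(g)
    try:
        fit = fit_inverse(hist)
        fit_out = {"a": fit.a, "r_squared": fit.r_squared}
    except ValueError:
        fit_out = None
    core = merge_cliques(g, merge_k)
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "degree_fit": fit_out,
        "max_clique_size": core.max_clique_size,
        "merge_k": merge_k,
        "merged_core_nodes": core.n_nodes,
        "merged_core_edge_fraction": core.edge_fraction,
    }
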