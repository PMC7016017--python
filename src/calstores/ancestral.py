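"""Dollo-parsimony ancestral gene-content reconstruction and
lineage-specific-expansion (LSE) flagging.

Under Dollo parsimony each protein family is gained exactly once on the
species tree and may subsequently be lost any number of times, but never
re-gained.  For a family observed (count >= 1) in a set of extant
leaves, the unique most-parsimonious single-gain history places the
gain at the most recent common ancestor of those leaves, with one loss
on the stem branch of each maximal all-absent subtree beneath the gain.
This is the most conservative reading of the data: the reconstructed
complement at any internal node — in particular at the root, the last
common ancestor of the sampled organisms — is a lower bound on the
ancestral repertoire.

Multifurcating trees are handled natively; presence is strict
(count >= 1), with no soft thresholds, since the matrix holds curated
paralog counts.

LSEs — duplication bursts confined to one clade — are flagged by a
median-based rule: a (family, clade) pair is reported when the median
count inside the clade is at least ``threshold`` times the median count
outside it (with the outside median floored at 1 so that families absent
elsewhere can still be flagged).  Medians resist single-genome outliers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .phyletic import CladeAnnotation, ParalogCountMatrix

logger = logging.getLogger("calstores")


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

class SpeciesTree:
    """Rooted species tree over organism identifiers (multifurcations allowed).

    Internal nodes keep their Newick labels when present and are
    otherwise auto-labelled ``N0, N1, ...`` in preorder (``N0`` is the
    root).  Leaf labels must be unique.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._label_nodes()

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(tree)

    @classmethod
    def from_file(cls, path: str | Path) -> "SpeciesTree":
        return cls.from_newick(Path(path).read_text())

    def _label_nodes(self) -> None:
        counter = 0
        self._by_label: dict[str, dendropy.Node] = {}
        for node in self._tree.preorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label if node.taxon else node.label
                if label is None:
                    raise ValueError("unlabelled leaf in species tree")
            else:
                label = node.label
                if label is None:
                    label = f"N{counter}"
                    node.label = label
                counter += 1
            if label in self._by_label:
                raise ValueError(f"duplicate node label {label!r} in species tree")
            self._by_label[label] = node

    @property
    def root_label(self) -> str:
        return self._node_label(self._tree.seed_node)

    def _node_label(self, node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label if node.taxon else node.label
        return node.label

    @property
    def leaf_labels(self) -> list[str]:
        return [self._node_label(lf) for lf in self._tree.leaf_node_iter()]

    @property
    def node_labels(self) -> list[str]:
        return [self._node_label(n) for n in self._tree.preorder_node_iter()]

    def node(self, label: str) -> dendropy.Node:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"no node labelled {label!r} in species tree") from None

    def postorder(self) -> Iterable[dendropy.Node]:
        return self._tree.postorder_node_iter()

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", unquoted_underscores=True, suppress_rooting=True
        ).strip()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Dollo reconstruction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyHistory:
    """Single-gain / minimal-loss history of one family on the tree."""

    family: str
    gain_node: str
    loss_branches: frozenset[str]  # identified by the child node of the branch
    present_nodes: frozenset[str]


@dataclass(frozen=True)
class DolloReconstruction:
    tree: SpeciesTree = field(compare=False)
    histories: dict[str, FamilyHistory] = field(default_factory=dict)
    skipped_families: tuple[str, ...] = ()

    @property
    def families(self) -> list[str]:
        return list(self.histories)


def dollo_reconstruct(t: SpeciesTree, m: ParalogCountMatrix) -> DolloReconstruction:
    """Reconstruct each family's gain node, loss branches and ancestral states.

    Presence at a leaf is ``count >= 1``.  Matrix organisms missing from
    the tree are ignored with a warning (the reconstruction then covers
    the sampled leaves only); a family absent from every tree leaf is
    skipped with a warning.
    """
    leaf_set = set(t.leaf_labels)
    matrix_orgs = set(m.organisms)
    ignored = matrix_orgs - leaf_set
    if ignored:
        logger.warning(
            "dollo: %d matrix organisms not in tree, ignored: %s",
            len(ignored), sorted(ignored)[:5],
        )
    missing_leaves = leaf_set - matrix_orgs
    if missing_leaves:
        logger.warning(
            "dollo: %d tree leaves absent from matrix treated as absent: %s",
            len(missing_leaves), sorted(missing_leaves)[:5],
        )
    org_index = {o: i for i, o in enumerate(m.organisms)}

    histories: dict[str, FamilyHistory] = {}
    skipped: list[str] = []
    post = list(t.postorder())
    for j, family in enumerate(m.families):
        # n_present[node] = number of present leaves in the node's subtree
        n_present: dict[int, int] = {}
        for node in post:
            if node.is_leaf():
                label = t._node_label(node)
                i = org_index.get(label)
                n_present[id(node)] = int(i is not None and m.counts[i, j] >= 1)
            else:
                n_present[id(node)] = sum(n_present[id(c)] for c in node.child_nodes())
        total = n_present[id(t.node(t.root_label))]
        if total == 0:
            skipped.append(family)
            continue
        # gain = MRCA of present leaves: the deepest node covering all of them
        gain = t.node(t.root_label)
        while True:
            full = [c for c in gain.child_nodes() if n_present[id(c)] == total]
            if len(full) == 1 and not gain.is_leaf():
                gain = full[0]
            else:
                break
        # losses: maximal all-absent subtrees strictly below the gain node
        losses: set[str] = set()
        present: set[str] = set()
        stack = [gain]
        while stack:
            node = stack.pop()
            present.add(t._node_label(node))
            for c in node.child_nodes():
                if n_present[id(c)] == 0:
                    losses.add(t._node_label(c))
                else:
                    stack.append(c)
        histories[family] = FamilyHistory(
            family=family,
            gain_node=t._node_label(gain),
            loss_branches=frozenset(losses),
            present_nodes=frozenset(present),
        )
    if skipped:
        logger.warning("dollo: %d families absent from all leaves, skipped: %s",
                       len(skipped), skipped[:5])
    return DolloReconstruction(tree=t, histories=histories, skipped_families=tuple(skipped))


def ancestral_complement(r: DolloReconstruction, node_label: str) -> frozenset[str]:
    """Families reconstructed as present at a tree node.

    At the root this is the lower-bound complement of the last common
    ancestor of the sampled organisms.
    """
    r.tree.node(node_label)  # raises KeyError for unknown nodes
    return frozenset(
        fam for fam, h in r.histories.items() if node_label in h.present_nodes
    )


def gains_losses_table(r: DolloReconstruction) -> pd.DataFrame:
    """Per-branch event table with columns branch, family, event.

    A branch is named by its child node; the gain row for a family sits
    on the branch leading into its gain node.
    """
    rows = []
    for fam, h in sorted(r.histories.items()):
        rows.append({"branch": h.gain_node, "family": fam, "event": "gain"})
        for br in sorted(h.loss_branches):
            rows.append({"branch": br, "family": fam, "event": "loss"})
    return pd.DataFrame(rows, columns=["branch", "family", "event"])


def write_complements(r: DolloReconstruction, path: str | Path) -> None:
    """TSV of (node, n_families, families) for every tree node."""
    rows = []
    for label in r.tree.node_labels:
        fams = sorted(ancestral_complement(r, label))
        rows.append({"node": label, "n_families": len(fams), "families": ",".join(fams)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Lineage-specific expansions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LSEFlag:
    family: str
    clade: str
    clade_median: float
    clade_max: int
    background_median: float


@dataclass(frozen=True)
class LSEReport:
    threshold: float
    flags: tuple[LSEFlag, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "family": f.family,
                    "clade": f.clade,
                    "clade_median": f.clade_median,
                    "clade_max": f.clade_max,
                    "background_median": f.background_median,
                }
                for f in self.flags
            ],
            columns=["family", "clade", "clade_median", "clade_max", "background_median"],
        )

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return {(f.family, f.clade) for f in self.flags}


def detect_lse(
    m: ParalogCountMatrix, ca: CladeAnnotation, threshold: float = 3.0
) -> LSEReport:
    """Flag (family, clade) pairs whose within-clade median count is at
    least ``threshold`` × max(1, median count outside the clade)."""
    if threshold <= 0 or math.isnan(threshold):
        raise ValueError("threshold must be positive")
    clades = sorted({ca.clade_of(o) for o in m.organisms})
    if len(clades) < 2:
        raise ValueError("LSE detection needs at least 2 clades")
    labels = np.array(ca.labels_for(m.organisms))
    flags: list[LSEFlag] = []
    for clade in clades:
        mask = labels == clade
        if not mask.any():
            logger.warning("detect_lse: clade %r has no organisms, skipped", clade)
            continue
        inside = m.counts[mask, :]
        outside = m.counts[~mask, :]
        for j, fam in enumerate(m.families):
            med_in = float(np.median(inside[:, j]))
            med_out = float(np.median(outside[:, j])) if outside.size else 0.0
            if med_in >= threshold * max(1.0, med_out):
                flags.append(
                    LSEFlag(
                        family=fam,
                        clade=clade,
                        clade_median=med_in,
                        clade_max=int(inside[:, j].max()),
                        background_median=med_out,
                    )
                )
    return LSEReport(threshold=threshold, flags=tuple(flags))
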