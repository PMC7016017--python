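"""Phyletic-profile analysis: Canberra distances, Ward clustering,
PCA/LDA ordination, and the polydomain score.

The Canberra distance between two count vectors p and q,

    d(p, q) = sum_i |p_i - q_i| / (|p_i| + |q_i|),

weights each coordinate by its magnitude, which makes it sensitive to
presence/absence and to proportional changes in small paralog counts —
the regime phyletic profiles live in.  A coordinate where both vectors
are zero contributes 0 (shared absence is zero dissimilarity).

Distances are clustered with Ward's agglomerative method, which merges
the pair of clusters whose fusion least increases the within-cluster
sum of squares.  The Canberra matrix is not Euclidean, so Ward here is
the Lance–Williams recurrence applied to the given distances; both the
squared-distance (ward.D2-style, default) and raw-distance
(ward.D-style) conventions are available.

The polydomain score summarises how amplified an organism's complement
is, weighted toward globally abundant families:

    f(p)  = log2( total count of family p / grand total ),
    PD(o) = sum_p c(o, p) * (f(p) - mean_p f(p)).

Organisms enriched in families that dominate the dataset score high;
organisms with reduced complements score low or negative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .phyletic import CladeAnnotation, ParalogCountMatrix, UNANNOTATED

logger = logging.getLogger("calstores")

Axis = Literal["organisms", "families"]
WardVariant = Literal["ward_d2", "ward_d"]


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def canberra(u: Sequence[float], v: Sequence[float]) -> float:
    """Canberra distance between two equal-length non-negative vectors.

    Coordinates where both entries are zero contribute 0.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    num = np.abs(u - v)
    den = np.abs(u) + np.abs(v)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(terms.sum())


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric matrix of pairwise distances with row labels."""

    labels: tuple[str, ...]
    D: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if D.shape != (n, n):
            raise ValueError(f"distance matrix shape {D.shape} != ({n}, {n})")
        if not np.allclose(D, D.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(D) != 0):
            raise ValueError("distance matrix diagonal not zero")
        if D.size and D.min() < 0:
            raise ValueError("negative distance")
        D = D.copy()
        D.setflags(write=False)
        object.__setattr__(self, "D", D)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.D, checks=False)


def pairwise_distances(m: ParalogCountMatrix, axis: Axis = "organisms") -> DistanceMatrix:
    """Full Canberra distance matrix over organisms (rows) or families (columns)."""
    if axis == "organisms":
        X, labels = m.counts, m.organisms
    elif axis == "families":
        X, labels = m.counts.T, m.families
    else:
        raise ValueError(f"axis must be 'organisms' or 'families', got {axis!r}")
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 1:
        return DistanceMatrix(labels, np.zeros((1, 1)))
    # scipy's canberra uses the same 0/0 := 0 convention
    D = squareform(pdist(X, metric="canberra"))
    return DistanceMatrix(labels, D)


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dendrogram:
    """Rooted binary merge tree from agglomerative clustering.

    ``linkage`` is a scipy-format (n-1) x 4 matrix: the first two columns
    are the merged cluster indices (leaves are 0..n-1, internal nodes
    n..2n-2 in merge order), the third the merge height, the fourth the
    size of the new cluster.
    """

    labels: tuple[str, ...]
    linkage: np.ndarray = field(repr=False)
    variant: str = "ward_d2"

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        Z = np.asarray(self.linkage, dtype=float)
        n = len(self.labels)
        if Z.shape != (n - 1, 4):
            raise ValueError(f"linkage shape {Z.shape} != ({n - 1}, 4)")
        Z = Z.copy()
        Z.setflags(write=False)
        object.__setattr__(self, "linkage", Z)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Newick string with merge-height differences as branch lengths."""
        tree = hierarchy.to_tree(np.asarray(self.linkage))
        labels = self.labels

        def rec(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0) if parent_height is not None else 0.0
            if node.is_leaf():
                return f"{labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            if parent_height is None:
                return f"({left},{right});"
            return f"({left},{right}):{length:.6g}"

        return rec(tree, None)

    def to_merge_table(self) -> pd.DataFrame:
        Z = self.linkage
        return pd.DataFrame(
            {
                "cluster_a": Z[:, 0].astype(int),
                "cluster_b": Z[:, 1].astype(int),
                "height": Z[:, 2],
                "size": Z[:, 3].astype(int),
            }
        )

    def write_merge_table(self, path: str | Path) -> None:
        self.to_merge_table().to_csv(path, sep="\t", index=False)


def ward_cluster(D: DistanceMatrix, variant: WardVariant = "ward_d2") -> Dendrogram:
    """Agglomerative Ward clustering of a precomputed distance matrix.

    ``ward_d2`` applies the Lance–Williams Ward recurrence to squared
    input distances and reports square-rooted heights (the convention of
    R's ``hclust(..., "ward.D2")`` and scipy); ``ward_d`` applies the
    recurrence to the raw distances (R's ``ward.D``).  The input need
    not be Euclidean; with Canberra distances the heights are a
    dissimilarity-based Ward criterion rather than true variance.
    """
    if D.n < 2:
        raise ValueError("ward clustering needs at least 2 items")
    y = D.condensed()
    if variant == "ward_d2":
        Z = hierarchy.linkage(y, method="ward")
    elif variant == "ward_d":
        # scipy's ward recurrence acts on squared inputs; feeding sqrt(d)
        # and squaring the heights yields the recurrence on d itself.
        Z = hierarchy.linkage(np.sqrt(y), method="ward")
        Z = Z.copy()
        Z[:, 2] = Z[:, 2] ** 2
    else:
        raise ValueError(f"unknown ward variant {variant!r}")
    return Dendrogram(D.labels, Z, variant=variant)


def cut_dendrogram(d: Dendrogram, k: int) -> dict[str, int]:
    """Cut into exactly ``k`` clusters; returns label → cluster id (0-based).

    Cluster ids are renumbered by order of first appearance along the
    label list, so the assignment is deterministic.
    """
    n = len(d.labels)
    if not 1 <= k <= n:
        raise ValueError(f"cannot cut {n}-leaf dendrogram into {k} clusters")
    raw = hierarchy.cut_tree(np.asarray(d.linkage), n_clusters=k).ravel()
    if len(set(raw)) != k:
        raise ValueError(f"tied merge heights prevent a cut into exactly {k} clusters")
    remap: dict[int, int] = {}
    out: dict[str, int] = {}
    for label, c in zip(d.labels, raw):
        if c not in remap:
            remap[c] = len(remap)
        out[label] = remap[c]
    return out


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrdinationResult:
    """Scores/loadings from PCA or LDA on organism complement vectors."""

    organisms: tuple[str, ...]
    variables: tuple[str, ...]
    scores: np.ndarray = field(repr=False)
    loadings: np.ndarray = field(repr=False)
    explained_variance_fraction: np.ndarray = field(repr=False)
    method: str = "pca"
    predicted_clades: tuple[str, ...] | None = None

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"{self.method.upper()}{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=list(self.organisms), columns=cols)


def pca(m: ParalogCountMatrix, n_components: int | None = None) -> OrdinationResult:
    """PCA on organism complement vectors, variables scaled to unit variance.

    Zero-variance families carry no ordination signal once scaled and are
    dropped with a warning.
    """
    if m.n_organisms < 2:
        raise ValueError("PCA needs at least 2 organisms")
    X = m.counts.astype(float)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all families have zero variance; PCA undefined")
    if not keep.all():
        dropped = [f for f, k in zip(m.families, keep) if not k]
        logger.warning("pca: dropping %d zero-variance families: %s", len(dropped), dropped)
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    n_comp = min(n_components or Xs.shape[1], Xs.shape[1], m.n_organisms - 1)
    model = PCA(n_components=n_comp, svd_solver="full")
    scores = model.fit_transform(Xs)
    total_var = Xs.var(axis=0, ddof=1).sum()
    evf = model.explained_variance_ / total_var
    variables = tuple(f for f, k in zip(m.families, keep) if k)
    return OrdinationResult(
        organisms=m.organisms,
        variables=variables,
        scores=scores,
        loadings=model.components_.T,
        explained_variance_fraction=evf,
        method="pca",
    )


def lda(
    m: ParalogCountMatrix,
    ca: CladeAnnotation,
    shrinkage: float = 0.1,
    n_components: int | None = None,
) -> OrdinationResult:
    """LDA trained on clade representatives, then applied to every organism.

    Representatives of each annotated clade are the prior groups; the
    fitted discriminants project and classify all organisms (including
    unannotated ones).  The within-class covariance is shrunk toward its
    diagonal (``shrinkage`` in [0, 1]) so the fit stays well-posed when
    families outnumber representatives per clade.
    """
    reps = [
        o
        for o in m.organisms
        if o in ca.representatives and ca.clade_of(o) != UNANNOTATED
    ]
    rep_labels = [ca.clade_of(o) for o in reps]
    groups = sorted(set(rep_labels))
    if len(groups) < 2:
        raise ValueError("LDA needs at least 2 prior groups with representatives")
    for g in groups:
        if rep_labels.count(g) < 2:
            raise ValueError(f"prior group {g!r} has fewer than 2 representatives")
    X = m.counts.astype(float)
    rep_idx = [m.organisms.index(o) for o in reps]
    model = LinearDiscriminantAnalysis(solver="eigen", shrinkage=shrinkage)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collinear count columns are routine
        model.fit(X[rep_idx], rep_labels)
        scores = model.transform(X)
        predicted = model.predict(X)
    n_comp = scores.shape[1] if n_components is None else min(n_components, scores.shape[1])
    evr = np.asarray(model.explained_variance_ratio_, dtype=float)[:n_comp]
    return OrdinationResult(
        organisms=m.organisms,
        variables=m.families,
        scores=scores[:, :n_comp],
        loadings=model.scalings_[:, :n_comp],
        explained_variance_fraction=evr,
        method="lda",
        predicted_clades=tuple(predicted),
    )


# ---------------------------------------------------------------------------
# Polydomain score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolydomainResult:
    organisms: tuple[str, ...]
    families: tuple[str, ...]  # families retained (positive total count)
    f: np.ndarray = field(repr=False)  # log2 family fraction of grand total
    f_bar: float
    PD: np.ndarray = field(repr=False)  # score per organism

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"organism": list(self.organisms), "PD": self.PD})

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def polydomain(m: ParalogCountMatrix) -> PolydomainResult:
    """Polydomain score PD(o) for every organism.

    f(p) is the log2 fraction of the grand total contributed by family p;
    PD(o) weights each organism's counts by the centred f.  Families with
    zero total count are dropped (their log2 fraction is undefined).
    """
    totals = m.counts.sum(axis=0)
    keep = totals > 0
    if not keep.any():
        raise ValueError("all-zero matrix: polydomain score undefined")
    if not keep.all():
        dropped = [f for f, k in zip(m.families, keep) if not k]
        logger.warning("polydomain: dropping %d zero-total families: %s", len(dropped), dropped)
    grand = totals[keep].sum()
    f = np.log2(totals[keep] / grand)
    f_bar = float(f.mean())
    PD = m.counts[:, keep].astype(float) @ (f - f_bar)
    families = tuple(fam for fam, k in zip(m.families, keep) if k)
    return PolydomainResult(m.organisms, families, f, f_bar, PD)


def signed_log10(x: np.ndarray) -> np.ndarray:
    """Sign-preserving log10 compression: sign(x) * log10(1 + |x|)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.log10(1.0 + np.abs(x))


def polydomain_histogram(
    r: PolydomainResult,
    subset: Sequence[str] | None = None,
    scale: Literal["linear", "signed_log10"] = "linear",
    bins: int | Sequence[float] = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of PD scores for a subset of organisms.

    Returns ``(counts, bin_edges)`` as from :func:`numpy.histogram`.
    ``signed_log10`` compresses the heavy right tail that strong
    lineage-specific expansions produce while keeping negative scores
    on the negative axis.
    """
    subset = list(subset) if subset is not None else list(r.organisms)
    if not subset:
        raise ValueError("empty organism subset")
    idx = {o: i for i, o in enumerate(r.organisms)}
    missing = [o for o in subset if o not in idx]
    if missing:
        raise KeyError(f"organisms not in result: {missing}")
    vals = r.PD[[idx[o] for o in subset]]
    if scale == "signed_log10":
        vals = signed_log10(vals)
    elif scale != "linear":
        raise ValueError(f"unknown scale {scale!r}")
    return np.histogram(vals, bins=bins)
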