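# Methods

This note records the models, conventions and design choices behind
calstores, in the spirit of the model documentation that simulation and
statistics packages ship alongside their APIs.

## Data model

The pipeline's central object is the paralog-count matrix c(o, p):
non-negative integer counts of paralogs of protein family p in organism
o. Rows are organism complement vectors, columns are family
distribution vectors; both views feed the same distance machinery.
Counts are assumed curated (one count per family per genome); the
package does not build matrices from raw proteomes. Organisms present
in a matrix but absent from a clade table are carried along with clade
`unannotated`: they are clustered, ordinated and classified, but never
used as LDA training priors.

## Canberra distances

d(p, q) = Σᵢ |pᵢ − qᵢ| / (|pᵢ| + |qᵢ|), with the convention that a
coordinate where both vectors are zero contributes 0 — shared absence
is zero dissimilarity. Each summand lies in [0, 1], so d ≤ vector
length; on the non-negative orthant the function is a metric (symmetry
and the triangle inequality are property-tested on random triples).
Pairwise matrices are computed with scipy's `pdist`, which uses the
same 0/0 convention; tests check it cell-by-cell against the package's
own scalar implementation.

## Ward clustering of non-Euclidean distances

Ward's method is defined for squared Euclidean geometry, but here it is
applied — deliberately — to Canberra distance matrices, as is common
with phyletic profiles: the Lance–Williams recurrence is evaluated on
the given dissimilarities and the resulting heights are a Ward-style
merge criterion rather than a true variance decomposition. Two
conventions are offered:

* `ward_d2` (default): the recurrence on squared input distances with
  square-rooted heights — what scipy's `linkage(method="ward")` and R's
  `hclust(..., "ward.D2")` compute;
* `ward_d`: the recurrence on the raw distances (R's `ward.D`),
  obtained by feeding √d to the scipy recurrence and squaring the
  heights.

Which convention a given published analysis used is often unstated;
both are provided so either can be reproduced. Merging is
deterministic given the input order (scipy's nearest-neighbor-chain
algorithm); heights are non-decreasing by construction and asserted in
tests. `cut_dendrogram` uses `cut_tree` to obtain exactly k clusters
and renumbers clusters by first appearance so assignments are stable.

## Ordination

PCA standardizes every family to unit variance first (families are on
very different count scales — a 100-copy kinase expansion would
otherwise swamp everything), dropping zero-variance families with a
warning. LDA is trained on clade *representatives* only and then
projects and classifies all organisms, mirroring the practice of
fitting discriminants on a trusted taxonomic backbone and classifying
the rest. Because the number of families can exceed the number of
representatives per clade, the within-class covariance is shrunk
toward its diagonal (scikit-learn `solver="eigen"`, shrinkage
λ = 0.1 by default, configurable). With λ = 0 the problem is often
singular; λ = 0.1 is a conventional light-regularization default, not a
fitted value. Two prior groups identical in feature space remain a
well-defined (chance-level) classifier provided the pooled within-class
scatter is non-degenerate.

## Polydomain score

f(p) = log₂ of family p's share of the grand total count; PD(o) =
Σ_p c(o, p)(f(p) − f̄). Families with zero total count are dropped
rather than pseudocounted, which keeps Σ 2^f = 1 exact; the score is
invariant to shifting all f(p) by a constant (the centering cancels it)
and scales linearly when all counts are multiplied — both are tested.
For histograms of PD a signed-log option x → sign(x)·log10(1 + |x|) is
provided, since PD can be negative and a plain log scale is undefined
there; this transform is this package's choice of a sign-preserving
compression, suitable for the heavy right tails that large
lineage-specific expansions produce.

## PPI network and the dense core

The graph is simple and undirected with edge classes
`literature_specific` > `literature_ambiguous` > `funcoup`; duplicate
input pairs collapse keeping the most specific class, self-loops are
dropped with a warning. All classes participate in degree and clique
analyses by default (`filter_edge_classes` restricts when needed).

The degree histogram is fit with the one-parameter rectangular
hyperbola N(d) = a/d by ordinary least squares over observed degrees
d ≥ 1 (closed form a = Σ N_d/d ÷ Σ 1/d²); R² = 1 − SS_res/SS_tot is
computed on the histogram counts and may be negative for profiles
flatter than their mean. Published fits of this kind rarely state
whether they were computed on raw degrees, binned counts or
frequencies, so moderate differences in R² against a published value
are expected; the form and the fit domain used here are fixed and
documented.

Maximal cliques come from networkx's Bron–Kerbosch-with-pivoting
enumeration, returned fully sorted for determinism and cross-checked
against a brute-force subset oracle on 200 random graphs of ≤ 12 nodes.
`merge_cliques(g, k)` takes the union of the nodes of all *maximal*
cliques of size ≥ k (merging all cliques of size ≥ k would give the
same union) and reports the induced subgraph and the fraction of the
whole network's edges inside it. No qualifying clique yields an empty
subnetwork with fraction 0, not an error.

## Dollo reconstruction

Presence at a leaf is count ≥ 1 — no soft thresholds, since the matrix
is curated. Each family is gained exactly once, at the MRCA of its
present leaves; one loss is placed on the stem branch of every maximal
all-absent subtree below the gain, so no loss branch has a descendant
loss for the same family. This single-gain model is the
fewest-assumptions reading of the data: ancestral complements —
including the root complement, the reconstructed core of the last
common ancestor of the sampled organisms — are lower bounds. It is
conservative for families with secondary horizontal transfer, which
are reported as reconstructed, not modelled specially. Multifurcations
are handled natively (no arbitrary resolution); the tree topology is an
input, with the synthetic `clade_tree` providing a deliberately coarse
clade-level rake when no resolved tree exists. An exhaustive
minimum-loss search over all (gain, loss-set) pairs on random ≤ 8-leaf
trees serves as the test oracle.

Lineage-specific expansions are flagged by a median rule: (family,
clade) is reported when the within-clade median count ≥ threshold ×
max(1, median outside the clade). The default threshold 3.0 is a
heuristic choice — large enough that Poisson noise around a shared
baseline never triples a median, small enough to catch genuine
duplication bursts; medians (not means) resist single-genome outliers,
and the max(1, ·) floor lets families absent elsewhere be flagged.
Raising the threshold never adds flags (tested).

## Synthetic generators

`gen_matrix` partitions organisms into near-equal clades and draws
counts Poisson(baseline × multiplier), where planted expansion events
multiply the mean of one family within one clade and planted loss
events zero that block. Defaults (100 organisms, 30 families, 4
clades, baseline rate 1, multiplier 5, first 3 organisms per clade as
LDA representatives) describe a dataset of the same order as a curated
several-hundred-genome study with clear but not overwhelming clade
structure: baseline Poisson(1) yields realistically patchy profiles
(≈ 37 % absences), and a 5× burst is a moderate LSE. A
negative-binomial option adds overdispersion. What the generator does
*not* emulate: phylogenetic autocorrelation within clades (counts are
i.i.d. given the clade), correlated gain/loss across families, and
genome-quality artifacts — so passing recovery tests demonstrates the
statistics behave as designed, not that real proteome curation is
error-free.

`gen_core_periphery` builds a dense Erdős–Rényi core (default 46 nodes
at p = 0.5) containing one planted clique (default 10 nodes, typed as
literature edges), plus a sparse periphery (default 127 nodes, one
guaranteed core link each plus Binomial extras at p = 0.02) — totals
chosen to mirror a 173-node curated interaction network with a dense
hub core. On such graphs the degree histogram follows an inverse law
rather than a power law, and clique-merging at k = 6 recovers the
planted core almost completely (≥ 95 % of core nodes across seeds).

Every generator takes an explicit integer seed and is fully
deterministic given it.

## Problem sizes and numerical conventions

Tests and the acceptance script use the generator defaults above
(100 × 30 matrices; 173-node graphs; 200 random ≤ 12-node graphs and
dozens of ≤ 8-leaf trees for the oracles), sizes at which every oracle
is exhaustive and the whole suite runs in seconds. Distance
equivalence is asserted to 1e-12; heights monotone to 1e-12; Dollo and
clique oracles exactly. Ward clade recovery is summarized over 20
replicate seeds: the mean adjusted Rand index exceeds 0.9, while a
single replicate occasionally dips to ≈ 0.87 when Ward splits one
clade boundary — an expected property of Ward on noisy Poisson
profiles, not a defect.

## Known limitations

* Ward heights on Canberra input are a merge criterion, not variances;
  do not read them as explained sums of squares.
* The inverse degree fit is a descriptive summary; no standard error
  or model comparison against power laws is provided.
* Ancestral *counts* (beyond presence/absence) are out of scope; only
  presence states are reconstructed.
* The plotting surface is minimal; dendrograms and scores are exported
  as Newick/TSV for external tooling.
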