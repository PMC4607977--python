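# Methods

This note documents the models and statistics implemented in `coexval`,
the defaults and why they were chosen, what the synthetic generator
does and does not emulate, and the numerical conventions that matter
for reproducing results.

## Network construction and module detection

Given a genes × samples expression matrix, the pipeline computes the
Pearson correlation between every gene pair (zero-variance genes are
assigned correlation 0 and logged), raises it to a soft-thresholding
power β (unsigned `|r|^β`, default β = 6, the common tutorial
convention for unsigned networks; a signed map `((1+r)/2)^β` is
available), and converts the weighted adjacency to the topological
overlap matrix

TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

which rewards shared neighbourhoods as well as direct connection.
Genes are clustered by average-linkage hierarchical clustering of
1 − TOM, and the tree is cut statically at a fixed height (default
0.99 of the maximum merge height).  A static cut was chosen over
dynamic tree cutting because it is deterministic and fully described
by one number; the cost is coarser modules on noisy data.  Clusters
smaller than `min_size` (default 3) are relabelled gray (unassigned);
surviving modules are named by the conventional colour sequence in
order of decreasing size.

Six global parameters summarise the binarized network (edge present
iff adjacency ≥ threshold; default threshold = median off-diagonal
adjacency, since export thresholds are study-specific): density,
mean local clustering coefficient over nodes of degree ≥ 2,
characteristic path length over connected pairs (disconnected pairs
are excluded, not infinite), degree heterogeneity sd(k)/mean(k),
Freeman degree centralization, and Newman–Girvan modularity Q of the
partition (gray genes as singleton communities by default).  An empty
binarized graph yields NaN markers, never zeros.

## Topology-based validation (Zsummary, medianRank)

Module preservation asks whether a module defined on a *reference*
dataset recurs in an independent *test* dataset.  Seven observed
statistics are computed per module — four density statistics on the
test data (mean within-module correlation, mean adjacency, proportion
of variance explained by the module eigengene, mean eigengene-based
connectivity kME, with the eigengene the first principal component of
the row-standardised module submatrix, oriented so mean kME ≥ 0) and
three connectivity statistics comparing reference and test per-gene
patterns (correlations of the kIM vectors, of the kME vectors, and of
the vectorised within-module correlations).  The `adjacency` mode
keeps only the sign-free mean adjacency and cor(kIM), for networks
without meaningful correlation signs.

Each statistic is standardised by a permutation null:
Z = (obs − mean_null)/sd_null over `n_perm` (default 200) random gene
sets of the module's size.  **The null pool is the tested module's
genes plus the gray genes.**  This is the exchangeability set of the
null hypothesis "this module is background-like", and two failure
modes of the alternatives drove the choice:

- *Pools disjoint from the module* (gray genes only) under-disperse
  the conditional null — all subsets of a fixed finite pool share that
  pool's realisation-specific structure, so a gene set from outside
  the pool lands many (collapsed) standard deviations away even when
  it is genuinely background (measured |Zsummary| up to ~7 for random
  background sets).  A valid permutation scheme must include the
  observed set in its pool.
- *The all-genes pool* mixes other modules' genes into every null
  set.  Null sets then carry a module-vs-gray composition gradient
  that is near-perfectly preserved between halves, which makes the
  null connectivity correlations structurally positive (~+0.8 with
  tight sd) and pushes Z negative even for perfectly preserved
  modules, and to ~−5 for background sets.  It remains available as
  `null_pool="all"`.

A consequence worth knowing: for a module that is large relative to
the gray pool, its own genes contaminate a sizeable fraction of the
null sets, which caps the connectivity Z near zero and makes Zsummary
size-dependent (the well-known density dominance of this statistic —
one reason medianRank exists).

Zdensity and Zconnectivity are the medians of their groups and
Zsummary their mean; Zsummary > 10 is strong, 2–10 moderate, < 2
unpreserved.  A zero-variance null or undefined statistic marks the
module `invalid` rather than producing ±∞.  medianRank ranks modules
per observed statistic (rank 1 = most preserved, ties share the mean
rank), takes the density and connectivity medians, and averages them;
it uses no permutation and is insensitive to module size.

Note that evaluating a module with reference = test degenerates the
connectivity statistics (observed and every null draw equal exactly
1), so self-preservation setups are uninformative by construction; use
a genuine sample split.

## Statistics-based validation (multiscale bootstrap AU)

Genes are clustered by correlation dissimilarity (1 − r) with average
linkage (the reference implementation's defaults; configurable).  For
each scale r in {0.5, 0.6, …, 1.4}, `n_boot` replicates resample
round(r·n) sample columns with replacement, the tree is rebuilt, and
an original internal-node cluster is counted when some replicate
cluster has exactly the same member set (exact matching keeps the
count deterministic).  With BP_r = count/n_boot and σ = √(1/r), the
probit-transformed curve z_r = Φ⁻¹(1 − BP_r) is fitted by weighted
least squares to

z_r = v/σ + c·σ,

with weights from the delta-method binomial variance of z_r.  The
signed distance v and curvature c give AU = 1 − Φ(v − c) and the
fitted BP at σ = 1 as 1 − Φ(v + c).  Scales with boundary counts
(0 or n_boot) carry no shape information and are dropped from the fit;
a cluster with fewer than two non-degenerate scales takes the majority
saturation rule (AU = 1 if present in at least half of all replicates,
else 0, flagged `saturated`).  A continuity-correction alternative
that clips boundary counts by 0.5/n_boot and keeps all scales is
available (`clip_boundary=True`); it was not made the default because
a run of saturated scales clipped to a common floor biases the fitted
curvature and visibly depresses AU for overwhelmingly supported
clusters.  Clusters with AU ≥ `threshold` (default 0.95) and at least
`min_size` genes are significant; nested significant clusters are all
reported, with a maximal-only filter available.

## Benchmark statistics and the gray-area experiment

For N datasets with per-dataset valid-module ratio R (valid =
Zsummary ≥ 2, or AU ≥ 0.95 with ≥ min_size genes; a dataset with no
computable statistic contributes R = 0):

- VSR = 100 · mean(R) — the unweighted mean of per-dataset ratios (a
  pooled-count alternative is available by flag);
- FR = 100 · sd(R)/mean(R), the coefficient of variation with the
  sample (n−1) standard deviation (plain sd by flag);
- VR = 100 · mean(|X_i − X₀|)/X₀ over perturbed re-runs of a count X
  (modules, gray genes, or valid modules), undefined when X₀ = 0.

The gray-area experiment freezes the baseline partition's gray set,
multiplies those genes' expression by each level in
{0.1, 0.5, 0.9, 1.1, 1.5, 2}, and re-runs detection and both
validation methods with identical seeds.  Because Pearson correlation
is invariant to positive rescaling of a gene's profile, the
perturbation cannot change the correlation structure; any change in
counts is attributable to nonlinearity of the pipeline (the clustering
cut).  With this package's static cut the pipeline is in fact exactly
scale-invariant, so VR = 0 at every level on synthetic data — the
experiment records this rather than asserting a change.  Pipelines
with data-dependent cut heuristics would show nonzero VR here.
Aggregation over datasets includes unchanged datasets by default; the
stricter convention that averages only changed datasets is available
(`include_unchanged=False`).

The per-dataset valid-module ratios are also regressed (ordinary least
squares, one parameter at a time) on the six network parameters,
reporting slope, Pearson r, and the two-sided p-value.

## Synthetic data generator

Each planted module follows a single-factor model: a latent factor per
sample, and gene i in module m has x_ij = ρ_i f_mj + √(1−ρ_i²) ε_ij
with ε iid N(0, noise_sd).  Per-gene loadings run down a relative
gradient ρ·(1+w) → ρ·(1−w) (default w = 0.3, clipped to (0, 1)),
emulating the hub-to-periphery range of eigengene correlations in real
modules (roughly 0.95 at the hub to 0.5 at the edge).  The gradient is
essential: with a single loading per module the genes are exchangeable
and the module has no intramodular connectivity structure for the
preservation statistics to measure.  Because the loadings are
symmetric around ρ and every gene has unit variance at noise_sd = 1,
the mean within-module correlation is still ρ²/(ρ² + (1−ρ²)·sd²) to
first order (measured 0.642 vs 0.640 at ρ = 0.8).  Gray genes are iid
normal, independent of all factors.  Generation is bit-reproducible
given the spec and seed.

What the generator does **not** emulate: probe/batch effects,
missing values, heavy-tailed noise, correlated background, overlapping
modules, or modules whose strength differs between reference and test.
Passing tests on this generator therefore demonstrate the statistics'
behaviour under a clean factor model, not robustness to microarray
artefacts.

Default study conditions (sizes 30/50/80 at ρ = 0.8, 60 samples split
30/30, 200 gray genes) mirror the smaller end of published spotted-array
co-expression studies.  Two behaviours of the preservation statistics
under these *equal-strength* conditions are worth stating plainly,
since they bound what the planted-module recovery test can show:
the largest module (80 genes vs a 200-gene gray pool) has ~29% of its
null sets self-contaminated, capping its Zsummary near the strong
threshold (exceeds 10 in roughly 70–80% of seeds, vs ~100% for the
30- and 50-gene modules); and with all modules equally strong, which
module tops Zsummary vs bottoms medianRank is decided by noise with
opposing size biases, so the two indexes agree on the best module only
about two thirds of the time — their agreement in real studies comes
from modules of genuinely different strength.

## Sample splitting and reproducibility

The reference/test split takes the first half of the columns by
default (odd counts put the extra sample in the reference); a seeded
random split is available.  Every stochastic stage — split,
permutation null, bootstrap — takes an explicit seed recorded in the
run config, report files embed the config hash, and identical configs
produce byte-identical JSON reports.

## Demonstration scale

The multi-dataset study used by the experiment driver and the
reproduction script runs ten synthetic datasets of three to four
modules (5–14 genes each) plus 40–50 gray genes over 40 samples, with
n_perm = 100 and n_boot = 50.  These sizes were chosen so the full
study, including the minimum-size sweep (3–10) and all six perturbation
levels, completes in about a minute while keeping every module large
enough for the statistics to be defined; they are the package's
demonstration conditions, not a claim about any published dataset.

## Known limitations

- Static tree cut only; no dynamic cut or block-wise detection for
  very large gene sets.
- The entropy index follows the within-module degree-distribution
  definition stated above; other entropy variants exist in the
  literature and are not implemented.
- AU cluster matching requires exact member-set equality; partial
  overlap matching was rejected for determinism.
- No multiple-testing adjustment across AU clusters (none is standard
  for this statistic).
- Zsummary is size-dependent by construction under any resampling
  null; compare modules of different sizes with medianRank.
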