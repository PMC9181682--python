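# Methods

## Scope and data model

`omicnet` analyzes two abundance layers — proteins and metabolite peaks —
measured on the same samples in a two-group (case/control strain) design.
The in-memory container is a feature-by-sample matrix with a per-feature
layer tag and a scale tag that may only advance along
`raw → log2 → quantile → unit-variance`. Missing values (NaN) model
mass-spectrometry dropouts and are confined in practice to the metabolite
layer.

## Normalization

Per layer: features with more than 30% missing values are dropped; values
are log2-transformed (`log2(v + offset)`, offset default 0; a non-positive
value with zero offset is a hard error naming the cell); optional quantile
normalization; unit-variance scaling (mean 0, sd 1 per feature, n−1
denominator; constant features dropped with a warning). Layers are then
concatenated, with colliding feature IDs prefixed by their layer tag and
sample order harmonized to the first layer.

Quantile normalization uses the row-means-of-sorted-columns reference with
the *average-ties* dialect: tied values within a column receive the mean of
the reference values at their tied ranks. Columns containing missing
values are mapped through the reference by fractional-rank interpolation.
Defaults follow the asymmetry of typical acquisition pipelines: quantile
normalization **on** for metabolite peak intensities, **off** for protein
intensities (only log transformation is standard there). A caveat
established on the synthetic data: when a large fraction of features load
on latent factors, quantile normalization partially removes the
between-sample shifts that *are* the signal (within-module correlation
dropped from ~0.77 to ~0.49 with 43% of features planted). With realistic
planted fractions the effect is minor, but the switch is per-layer
configurable for exactly this reason.

Outlier screening is report-only: samples are scored on the first two
principal components and flagged when their distance from the score-space
centroid exceeds `k_sd` (default 3) times the standard deviation of those
distances. The pipeline writes the flags and, only when configured,
re-runs without the flagged samples; it never silently mutates data.

## Differential abundance

log2FC = mean(case) − mean(control) on the log2 scale. The metabolite
convention is the Welch unequal-variance t with Satterthwaite degrees of
freedom; the protein convention is an empirical-Bayes moderated t. The
moderated t shrinks each feature's pooled variance s² (d = n₁+n₂−2 df)
toward a prior s₀² with weight d₀:

    s̃² = (d₀·s₀² + d·s²) / (d₀ + d),   t̃ df = d₀ + d.

(d₀, s₀²) are fitted by the method of moments to the observed variance
ensemble under the scaled-F model s²/s₀² ~ F(d, d₀): with
c = Var(s²)/Mean(s²)² · d/2, d₀ = (d + 4c − 2)/(c − 1), and d₀ = ∞ (all
variances shrunk to the mean) when c ≤ 1. Degenerate conventions: equal
zero-variance groups give t = 0, p = 1; unequal means with zero variance
give p = 0 (logged).

Benjamini–Hochberg adjustment is the exact step-up rule
(q₍ᵢ₎ = min_{j≥i} m·p₍ⱼ₎/j, clipped to 1). The volcano caller labels a
feature up/down only when |log2FC| > log2(1.5) — the threshold is on the
raw fold scale — and q < 0.05. Both thresholds are configurable; the
output table carries log2FC and the signed raw fold (−2^|log2FC| for
decreases) because published tables print either.

## Network and modules

Pearson correlations are computed over pairwise-complete samples (pairs
with fewer than 4 complete observations are recorded missing and get
adjacency 0). Adjacency defaults to the literal unsigned β = 1 reading
(a = |r|); soft-thresholding powers and the signed variant are available.
Topological overlap is deliberately not applied.

Module detection starts from average-linkage clustering of d = 1 − |r|
cut at the 0.85 quantile of the dendrogram's merge heights, giving
candidate cores (≥ 5 members). At small n a static cut alone is brittle:
the realized variance of a module's latent factor varies so much at
n = 12 that modules fragment, dissolve, or absorb noise at any fixed cut.
Two refinement steps (2 cycles, both optional and on by default when the
data matrix is supplied) fix this:

1. **Ratio merge** — merge the cluster pair maximizing
   mean|r|(between) / √(mean|r|(within A) · mean|r|(within B)) while it
   exceeds 0.7. Normalizing by the within-cluster strength makes
   fragments of one weakly realized module reunite (ratio ≈ 1) while
   distinct modules stay apart (ratio ≈ 0.3–0.6).
2. **kME reassignment** — every feature joins the module whose eigengene
   it correlates with most strongly, kept only at |kME| ≥ 0.8, otherwise
   grey.

Clusters below `min_size` (default 10) end up grey; survivors are named
from the standard color vocabulary in decreasing size order, ties broken
by smallest member ID, which makes partitions permutation-stable and
deterministic. On planted five-module data (sizes 15–40, loading 1, noise
sd 0.7, n = 6+6) the refined partition attains a mean adjusted Rand index
of ~0.95 against truth over 20 seeds, and pure-noise matrices come out
essentially fully grey. Weakly realized modules are sometimes dropped
entirely to grey rather than reported wrongly — a deliberate
precision-over-recall choice.

The module eigengene is the leading right-singular vector of the
standardized member submatrix, scaled to unit sd and oriented so the mean
member correlation is non-negative. kWithin sums a feature's adjacency to
its module co-members (diagonal excluded); grey features are never hub
candidates.

## Traits and hubs

Module–trait association is the Pearson correlation of eigengene against
trait with the analytic Student-t p (df = n−2, two-sided); the 0/1 strain
indicator makes this the point-biserial correlation, and a permutation p
is available as a cross-check. No multiple-testing correction is applied
across the module–trait grid (raw p-values are reported, as is
conventional for these heatmaps).

The hub combines the two published criteria — highest degree centrality
and strongest eigengene-correlation significance — by rank sum, with ties
resolved by smaller kME p then lexicographic ID; modules under 3 members
are flagged low-confidence. **Known limitation:** at n = 6+6 hub
identification is noise-limited. With a hub loading of 1.5 vs member
loadings of ~0.8–1, the hub's population kME (~0.95) exceeds the members'
(~0.85) by less than the sampling noise of a correlation at n = 12
(Fisher-z sd ≈ 0.33), so even an oracle ranking members by correlation
with the *true* latent factor picks the planted hub in only about half of
runs (about one in five under the harder five-module conditions). The
reported hub is best read as "a representative of the module's most
central members" rather than a uniquely determined node at this sample
size.

## Overlap

Two partitions are cross-tabulated over the **intersection** of their
feature universes (only features present in both networks can overlap;
p-values are universe-sensitive, so the universe is explicit). Each cell
uses the one-sided hypergeometric upper tail P(X ≥ k), identical to the
one-sided Fisher exact test of the collapsed 2×2 table, evaluated by
log-sum-exp over log-pmf terms so that magnitudes far below float
underflow (1e-46 and beyond) are exact in −log10 space.

## Enrichment

Over-representation uses the same hypergeometric tail against GMT sets
intersected with an explicit, caller-supplied universe (sets retaining
fewer than 2 universe members are skipped), BH-corrected across sets.
Protein and metabolite identifiers may appear in one set, giving a joint
multi-omic query; no identifier mapping is attempted — inputs must share
a namespace with the GMT.

The quantitative score down-weights promiscuous features: with f_g = the
number of sets containing feature g, w_g = 1 + √((f_max − f_g)/(f_max −
f_min)) (all weights 1 when frequencies are uniform). A set's score is
the mean over quantified members of w_g·|t̃_g|. Significance comes from
group-label permutations with full re-scoring, scores standardized across
sets within each permutation (skipped when only one set survives), and
p = (1 + #{perm ≥ observed})/(n_perm + 1), which is never below
1/(n_perm+1). Under a pure null the empirical type-I error at 0.05 is
~0.04–0.055 (slightly conservative from permutation granularity at
n_perm = 150). Pathway direction is the unweighted mean member log2FC.

## Synthetic data

The generator emulates the statistical structure of a 6-vs-6 two-strain
multi-omic study. Per planted module k, a latent factor
z_k(s) ~ N(δ_k·group(s), 1) drives its members:
log2 x_i(s) = baseline + α_i·z_k(s) + N(0, σ). One designated hub member
receives an elevated loading, making it both the most connected node and
the feature most correlated with the module eigengene in expectation.
Background features are baseline + noise; raw intensities are 2^log2x
(log-normal); metabolite entries are masked missing completely at random.
Traits are linear in the latent factors plus N(0, 0.5) noise; strain is
the exact 0/1 label; seizure traits are forced to 0 in every control
sample (controls are seizure-free by construction). A single explicitly
seeded generator stream produces bit-identical output per seed.

Defaults (`study_config`): n = 6 per group, 200 proteins + 100
metabolites, five planted modules of sizes 15–40 with loading 1.0, hub
loading 1.5, noise sd 0.7 on the log2 scale, baseline 20; one "disease"
module with a between-strain factor shift δ = 2 and trait coefficients
+1 on the seizure traits and −1 on the behavioral traits. Noise sd and
baseline are conventions, not estimates from any real dataset. Closed
forms used in validation: within-module pairwise correlation
α²/(α²+σ²); noiseless member covariance α_i·α_j·var(z).

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: batch and chromatographic drift, intensity-
dependent missingness (MNAR), heavy-tailed feature noise, correlated
background, more than one factor per feature, and identifier ambiguity.

## Pipeline, determinism, problem sizes

The pipeline stages are preprocess → differential → network → module–
trait/hubs → (two regions) overlap → enrichment, each writing plain-text
TSV/JSON artifacts and finishing with a manifest of SHA-256 output hashes;
identical config + seed reproduce identical hashes. Stage-level
randomness derives from the global seed plus a CRC-32 stage-name salt,
kept below 2³¹. Validation experiments run at deliberately modest sizes —
300-feature networks, 20 replicate seeds for recovery, 200 replicates for
null calibration, 150–500 permutations — chosen so the full suite
completes in about a minute while keeping Monte-Carlo error well inside
the asserted margins.
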