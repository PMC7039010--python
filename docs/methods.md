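# Methods

This note documents the statistical procedures implemented in
`exprstream`, the defaults and their rationale, the numerical edge-case
policies, and what the synthetic-data generator does and does not
emulate.

## Data model and out-of-core contract

The data file is delimited text (TSV by default, CSV supported; UTF-8;
LF or CRLF), one row per feature: a unique feature-ID column, optional
feature-metadata columns, and one numeric column per sample. Indexing
makes a single streaming pass that records each line's byte offset and
length, validates that every numeric token parses (the tokens `""`,
`NA`, `NaN`, `null` are missing by default), and rejects duplicate IDs
and ragged rows with coordinates. Reading a feature is then one seek
plus one line read; scans visit rows through a single open handle, so
peak memory is O(rows + columns) for the index itself plus one row,
never O(rows × columns). The index is persisted in a JSON sidecar
together with the data file's size and SHA-256 of its first and last
64 KiB; any mismatch at load time forces re-indexing rather than
serving stale offsets.

Feature-metadata columns are those named explicitly, or — when inferred
at project creation — columns absent from the sample-metadata table
whose first-row token is non-numeric. A *numeric* column with no
sample-metadata row is deliberately left as an expression column so
that the orphan-column check fails loudly: silent reclassification
would hide a truncated metadata file. Sample-metadata rows without a
matching expression column are retained with a warning (a compilation
may describe more samples than a particular matrix export contains).

The recorded transform is `log2(x + c)` with pseudocount c = 1 by
default (zeros are routine in RNA-Seq-derived matrices); arguments ≤ 0
become missing and are counted in a warning counter rather than raising,
since a handful of negative normalized values should not abort a scan.
Missing values propagate as missing, and every pairwise statistic uses
pairwise-complete observations with the complete count reported as n.

Sample and feature predicates are pandas `query` expressions evaluated
with the python engine, which covers equality, inequality, membership,
substring (`field.str.contains(...)`), numeric comparison and and/or
conjunction; unknown fields raise a `PredicateError` naming the field.
The expression filter "value > v in ≥ k samples" streams rows and never
materializes the matrix.

Projects serialize to a versioned zip archive containing the project
state (transform, named groups with their predicates, saved result
tables with parameters), the embedded sample-metadata table and a copy
of the index sidecar; the data file is referenced by absolute path and
never embedded, so archives stay small and the single source of truth
for expression values remains the original file.

## Association statistics

Pearson r uses the sample product-moment formula with the two-sided
parametric p from the t distribution on n − 2 df; Spearman is Pearson
on mean-ranked data. Fewer than 3 complete pairs, or a constant vector
on the complete subset, is an *undefined correlation error* — returning
r = 0 would conflate "no evidence" with "evidence of independence". In
feature-vs-all scans the same conditions produce a missing statistic
with the feature retained in the output. Ranked outputs order by
descending statistic with ties broken lexicographically by feature ID,
so results are reproducible across runs, worker counts and on-disk
orderings.

The sample-QC screen computes all within-group pairwise Pearson
correlations across features in one streaming pass, accumulating
pairwise-complete sufficient statistics (per-pair n, sums, squares and
cross-products), and flags a sample only when *all* of its within-group
correlations fall below the threshold (default 0.70) — a single poor
partner should not condemn a sample.

## B-spline mutual information and CLR

MI is estimated in bits by soft binning: each observation is linearly
mapped from its [min, max] range onto the spline domain [0, M − k + 1]
and assigned M weights from the order-k B-spline basis on a uniform
knot vector with k-fold endpoint multiplicity (Cox–de Boor recursion;
the basis matches `scipy.interpolate.BSpline.design_matrix` to ~1e-12
and is a partition of unity). Marginal bin probabilities are per-bin
mean weights; the joint is the mean outer product, so the marginals of
the joint equal the marginal estimates by construction and the plug-in
MI is non-negative up to rounding. Defaults M = 10 bins, k = 3
(quadratic), the canonical settings of the B-spline density approach;
k = 1 reduces exactly to the hard-binned histogram estimator.

Two properties matter for interpretation. First, the estimator measures
the MI of the *soft-binned* variables: smoothing mixes adjacent bins,
and the linear min–max mapping compresses heavy-tailed data toward the
middle bins, so the value is a resolution-limited lower bound on the
continuous MI. For a bivariate Gaussian with ρ = 0.9 (analytic MI
≈ 1.20 bits), hard binning at M = 10 yields ≈ 0.95 bits and the default
soft binning ≈ 0.45–0.59 bits depending on n. Absolute MI values should
therefore be compared only within one estimator setting; rankings,
permutation p-values and CLR are unaffected by the monotone bias.
Second, constant vectors are special-cased to exactly 0 (the joint
factorizes; floating-point products would leave ~1e-16 residue). Fewer
complete observations than M yields a flagged low-n estimate with a
warning. MI p-values are available only by permutation (shuffle one
vector, re-estimate, (1 + c)/(B + 1)), as no parametric null is
implied by the estimator.

CLR standardizes each pair's MI against the background of both
partners: μ_i and σ_i are taken over feature i's off-diagonal MI row,
z clamped at zero, CLR_ij = √(z_i(j)² + z_j(i)²). A zero-variance
background defines z = 0 (documented degenerate case). This discounts
promiscuous features whose MI is elevated with everything.

## Meta-analysis of correlations

Per-study correlations are pooled on the Fisher-z scale: z_i =
atanh(r_i) with variance 1/(n_i − 3), fixed-effects weights w_i =
n_i − 3 ("proportional to the sample size" up to the small-sample
correction), Cochran's Q for heterogeneity, and the DerSimonian–Laird
moment estimator τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)) for the
random-effects model. Pooling on the z scale keeps the back-transformed
estimate inside (−1, 1) and is the standard Hedges–Olkin approach;
pooling raw r would not be variance-stabilized. Studies with n ≤ 3 or
|r| = 1 are rejected (infinite z / undefined variance). The
implementation reproduces R `metafor` (ZCOR + FE/DL) to ~1e-9 on fixed
inputs, frozen in the test suite.

## Two-group tests and the DE rule

Defaults follow large-sample practice: Mann–Whitney U uses the
tie-corrected normal approximation with continuity correction, with
exact enumeration of all C(n, n_a) label arrangements auto-selected for
total n ≤ 12 (enumeration on mid-ranks handles ties; "as extreme" means
|U − n_a n_b/2| at least the observed deviation). Wilcoxon signed-rank
drops zero differences, mean-ranks tied magnitudes, and enumerates all
2^m sign assignments for m ≤ 12 non-zero differences. Degenerate inputs
have defined outcomes: all-tied data gives p = 1 with a warning; zero
variance with unequal means returns the smallest positive double with a
warning rather than a spurious zero.

Permutation tests permute group labels (independent design) or flip
pair signs (paired), default statistic the difference of means (mean
difference when paired), and report p = (1 + #{|T_b| ≥ |T_obs|})/(B+1)
— never zero, and exact in expectation. Each permutation b draws its
randomness from a counter-based Philox generator keyed by (seed, b), so
a partitioned parallel run reproduces the serial stream bit for bit.

`de_scan` streams all features, computes the chosen test plus logFC
(difference of group means on the log2 scale; on raw-scale data,
log2 of the ratio of means with the project pseudocount), adjusts
across all tested features, and calls a feature when |logFC| ≥ 1 and
BH-adjusted p < 10⁻³ (defaults; both bounds configurable). Groups
smaller than 30 trigger a warning, not a refusal — these are
large-sample methods, and count-model DE (edgeR/DESeq2/limma-style
model fitting) is explicitly out of scope. Per-feature permutation
seeds derive from crc32(feature_id) XOR the run seed, making results
independent of on-disk row order; output tables are sorted by feature
ID. The stage scan applies the same machinery per organ to a candidate
list, comparing late-stage versus early-stage samples at |logFC| ≥ 1
and BH p < 0.05, labelling features increasing, decreasing or flat;
organs or features with fewer than two observations per stage group are
skipped with a warning.

## Differential correlation

For target t and every other feature, the parametric mode computes
group correlations r₁, r₂ on pairwise-complete data (the complete n,
not the nominal group size, enters the variance), Fisher-transforms
them, and tests Z = (z₁ − z₂)/√(1/(n₁−3) + 1/(n₂−3)) against the
standard normal. The distribution-free mode permutes the pooled group
labels B times (counter-based seeding) and uses T = r₁ − r₂ with the
empirical p convention; the same label permutations are applied to
every feature, mirroring a label-exchange null. Both modes BH-adjust
across features. The raw-difference test has no standard parametric
null, so permutation is the only distribution-free realization offered.

## Multiple testing

Bonferroni (min(1, m·p)), Holm (step-down with running max) and BH
(step-up with running min) return adjusted p-values; thresholds are a
downstream decision, matching how corrected p-value cutoffs are
reported. Missing p-values are excluded from m and returned missing;
sorting ties break by original index for determinism. Holm's adjusted
values never exceed Bonferroni's, so Holm's rejections are always a
superset at any α.

## Synthetic data generator

The generator emulates the structure of multi-study tumor/non-tumor
compilations: values on a log2-normal scale (per-feature baseline mean
~ N(8, 2), unit noise sd by default), samples assigned round-robin to
studies and block-wise to organs, each organ split into non-tumor and
tumor halves, tumor samples cycling stages I–IV. Planted effects:

* co-expression modules via a shared latent factor with loading √ρ, so
  every within-module pair has model correlation exactly ρ;
* DE features with a fixed logFC added to tumor samples (default 2,
  i.e. a 4-fold change, with noise sd 0.5 — the high signal-to-noise
  regime in which the calling rule should achieve full recall with no
  false calls);
* a differential-correlation pair with partner = ρ_g·t + √(1−ρ_g²)·ε
  per group, giving correlation ρ_g exactly in the model;
* stage-trend features with a fixed mean increment per stage;
* optionally a promiscuous hub: every feature loads √ρ_hub on a global
  factor which the hub itself *is*, giving hub–other correlation ρ_hub
  and other–other correlation ρ_hub² (the CLR benchmark).

Per-feature random streams are counter-based (Philox keyed by seed and
feature index), so generation is deterministic, byte-identical per
seed, and parallelizable. The generator does **not** imitate RNA-Seq
count distributions (no negative-binomial sampling, library-size or
batch effects, no mean–variance trend): the engine consumes normalized
values, and tests passing on Gaussian log-scale fixtures demonstrate
the statistical machinery, not robustness to raw-count artefacts.

## Problem sizes and calibration checks

The acceptance script and test suite use: 20 random index fixtures with
shapes drawn up to 5,000 × 1,000 (one at the cap); 1,000 random inputs
per statistic oracle; exhaustive rank-test enumeration for all total
n ≤ 10; 1,000-replicate null simulations per test for type-I error
(permutation test at n = 20/group with B = 999; rank and t tests at
n = 30/group; differential correlation at n = 50/group with common
ρ = 0.5), judged against the central 99% binomial band around α = 0.05;
500 replicates of 10 studies × n = 100 for meta-analysis recovery; 20
seeds for DE planted-truth recovery and 100 replicates each for the CLR
and differential-correlation benchmarks. These sizes give Monte-Carlo
margins well below the effect sizes being checked while keeping the
full run in the order of a minute or two.

## Known limitations

* Absolute MI values are estimator-specific (see above); no bias
  correction (e.g. shuffle subtraction) is applied beyond permutation
  p-values.
* No >2-group designs, no count-model DE, no network clustering or
  visualization (edge lists are exported for external tools), no
  normalization or batch correction — input is assumed normalized.
* The sample-wise (column) operations stream all rows rather than
  maintaining a transposed index; a column-heavy workload pays one full
  pass per scan by design (no doubled disk footprint).
* Thread-based parallelism shares the GIL; it helps when scipy releases
  the GIL in inner loops but is primarily a determinism-preserving
  partitioning contract, not a throughput guarantee.
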