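# Methods

This note documents the statistical model behind `mrcoex`, the estimators
it implements, the synthetic data model used for validation, and the
numerical and design choices a maintainer would want to know. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Coexpression pipeline

**Preprocessing.** Raw intensities/counts are transformed as
log2(v + c) with pseudocount c = 0.125 (so zero maps to −3); the
pseudocount keeps zeros finite while leaving moderate values essentially
unchanged. Because compendia aggregate many independent experiments, the
experiment is the batch unit. Two corrections are provided:

* *Batch zero-centering* — subtract each gene's per-experiment mean.
  Idempotent; the classical correction.
* *Empirical-Bayes location/scale adjustment* — a one-step parametric
  scheme in the ComBat family. Per gene, the matrix is standardized by
  its pooled within-batch residual SD; per batch b, the location effect
  γ_gb (batch mean of the standardized data) and squared scale effect
  δ²_gb (batch variance) are estimated, then shrunk toward across-gene
  priors fitted by the method of moments — normal for γ (posterior
  mean (n_b τ² γ̂ + δ̂² γ̄)/(n_b τ² + δ̂²)) and inverse-gamma for δ²
  (posterior mean (θ + ½·SS)/(n_b/2 + λ − 1)) — and removed as
  z* = (z − γ*)/δ*. This is deliberately simpler than full ComBat: one
  step rather than the iterative EB, parametric priors only, and no
  covariate design matrix. Any external batch-correction implementation
  can be substituted, since only the adjusted matrix flows downstream.
  Direct (non-EB) variance standardization is intentionally not the
  default: it destroys fold-change information; shrinkage is what makes
  scale adjustment safe. Singleton batches fall back to location-only
  with a logged warning. Outputs are reported per-gene centered (Pearson
  correlation is location-invariant, so downstream results are
  unaffected); with shrinkage disabled, location-only adjustment *is*
  batch centering, exactly.

Multi-probe platforms are resolved either by averaging a gene's probes or
by selecting the probe whose coexpression profile (correlation vector
against the single-probe "anchor" genes) best agrees — by Pearson
correlation of profile vectors — with the same gene's profile in a
reference network from an independent platform. The similarity metric is
a design choice; profile-vector Pearson is the most direct reading of
"similarity of coexpression patterns". Genes absent from the reference
fall back to averaging. Zero-variance genes are dropped (logged) before
correlation, since Pearson correlation is undefined for them.

**Mutual rank.** From the all-pairs Pearson matrix, each guide gene i
ranks its N−1 partners by *descending signed* correlation: the most
positive partner gets rank 1, the most negative rank N−1. Ranking by
signed r (not |r|) makes negative coexpression land at the high-MR end of
the range, which is where its instability is visible in the error
profile. Ties receive average (fractional) ranks, so the result is
deterministic and permutation-invariant. Then MR_ij = √(R_ij·R_ji),
symmetric, bounded by the two ranks, in [1, N−1]. The diagonal is masked:
a gene is never its own coexpression partner. The vectorized
implementation is required (and tested) to agree exactly with a naive
per-pair loop-and-sort implementation; computation is dense in memory,
targeted at desk-scale networks (≤ a few thousand genes); the contract
leaves blocking/streaming open for larger N.

**Logit scale.** p = MR/N ∈ (0,1) and logit(p) = log(p/(1−p)). With
p = (r+1)/2 this is exactly the Fisher transform doubled, which motivates
treating logit-MR errors as normal. `inverse_logit_mr` (N·sigmoid z) is
the exact inverse, used for confidence-interval back-transform and the
logit average.

## Bootstrap over experimental units

Each replicate draws experiments with replacement until the original
*experiment count* is reached, then re-runs batch correction and the full
MR pipeline. The resampling unit is a design decision exposed as a flag
(`experiments`, the default, or `samples`): resampling experiments
respects the batch structure that dominates compendium noise, and
"the same number of samples" is then satisfied in expectation. Repeated
draws of one experiment are treated as distinct batches — each draw is an
independent pseudo-experiment — and their samples are renamed (`s#k`) to
keep IDs unique. The probe map, when used, is fixed before bootstrapping
and not re-selected per replicate.

Per-pair moments of MR and logit-MR across replicates are accumulated in
a single pass (Pébay's streaming update for central moments up to order
4), so B matrices never coexist in memory; the streaming results are
tested against two-pass computation. B defaults to 100; tests and the
acceptance script use B = 20–30, which resolves the SD field and the
per-bin medians at the problem sizes used. One top-level seed feeds a
`SeedSequence`; per-replicate substreams are spawned from it, making the
whole summary reproducible bit-for-bit.

**Error profiles.** Pairs are assigned to non-overlapping percentile bins
(default width 0.01) of their mean bootstrap MR; each bin reports the
median and quartiles of the SD on the chosen scale. On synthetic data the
raw-MR SD peaks mid-range (uncorrelated pairs) and collapses at both
extremes, while the logit-MR SD is near-constant — the property that
justifies a single per-platform error number σ. Per-bin skewness and
excess kurtosis of the replicate deviations (from the same streaming
accumulators, B ≥ 4) quantify non-normality: on the raw scale skewness
sweeps from positive (small-MR end, hard lower bound at 1) through zero
to negative (large-MR end); on the logit scale it stays near zero
throughout. Because raw-scale skewness crosses zero at the median, the
mid-range normality comparison is made over the central 0.3–0.7
percentile window, not a single 0.5 bin.

**Error model.** Across platforms, mean logit-MR error is regressed on
log(sample count) by least squares; the model stores the Pearson r of the
two variables and predicts σ for unseen platforms. The package bundles
the published summary statistics of 16 public plant coexpression
platforms (genes, samples, logit-MR error, function score) as
`PLATFORM_SUMMARY` to anchor this relationship without any download.

**Bagging.** The bagged MR matrix is the equal-weight logit average of
the replicate matrices — the mean of logit-MR back-transformed — chosen
over the arithmetic mean for consistency with how MR values are
integrated everywhere else (an arithmetic mode exists for comparison).
Values stay in (0, N); with one replicate, bagging returns that
replicate.

## Integration and confidence intervals

The weighted logit average is evaluated in log space
(N·sigmoid(Σwᵢ log MRᵢ − Σwᵢ log(N−MRᵢ))), which cannot overflow for any
k and is algebraically identical to the product form and to the
inverse-logit of the weighted mean of logits (the identity is the core
correctness test, checked to 1e-12). Weights must be positive and sum to
1 within 1e-6 (renormalized with a warning inside that tolerance,
rejected outside). The geometric-mean form Πmrᵢ^wᵢ is provided as the
MR ≪ N approximation; its relative gap to the exact average shrinks as N
grows with the MRs fixed.

Confidence intervals back-transform logit(MR/N) ± z·σ with the standard
normal quantile z = Φ⁻¹((1+level)/2) (1.6449 at the default 90% level).
The quantile is an explicit parameter: published interval tables for
typical MR values are close to but not exactly reproducible by the
two-sided normal construction, and their exact recipe is not derivable
from the text, so this package makes the construction explicit rather
than matching such tables numerically. For MR ≪ N the logit degenerates
to a log, so intervals are multiplicatively near-symmetric. Nominal
coverage under the logit-normal model is verified by simulation. σ = 0
collapses the interval to the point value.

## Network quality

**Reproducibility.** Each platform's edge set is the union over genes of
their k = 3 smallest-MR partners, as undirected pairs (the
network-drawing convention; directedness is not meaningful for an
undirected similarity). Ties at the k-th position are broken by
(MR, partner ID), making selection deterministic. Before comparison both
edge sets are restricted to the genes the platforms share; the score is
the Jaccard coefficient of the restricted sets.

**Function score.** All pairs of annotated genes present in the matrix
are labeled positive if they share ≥ 1 term, negative otherwise — the
literal two-group division; no paralog filtering is applied (paralogous
pairs legitimately share function and expression). Pairs are ranked by
ascending MR; the ROC is built with tied MR values advancing as one
diagonal block (midrank/trapezoid handling, so the score is invariant
under any strictly monotone transformation of MR and under permutation of
tied pairs); the area up to FPR = 0.01 is linearly interpolated at the
cutoff and scaled by (1/0.01)² = 10,000. A random ranking has expected
partial area 0.01²/2, hence score 0.5; perfect early retrieval gives 100.
The implementation is cross-checked against an independent ROC
construction (scikit-learn's `roc_curve` plus explicit clipped
trapezoids) in the tests.

**Annotation filtering.** Terms are size-filtered before scoring to keep
information content high: GO-style mode keeps terms with *fewer than* the
bound (default < 50 genes); pathway-style mode excludes terms with *more
than* the bound (default > 100 excluded, = 100 kept). The gene universe
becomes the genes with ≥ 1 surviving term. Both bounds are configurable.

## Synthetic data model

Each of M modules has one latent factor per sample; a gene in module m
has log-scale expression

  baseline_g + a·f_m(s) + batch_g,e + ε, ε ~ N(0, σ_noise²),

with loading a, per-(gene, experiment) batch offsets ~ N(0, σ_batch²)
applied on the log scale (where batch correction operates), optional
per-(gene, experiment) multiplicative distortion of the noise SD, and the
result exponentiated base 2 so the raw matrix is strictly positive and
the standard log transform recovers the linear model up to the
pseudocount. The rank-1 construction gives the closed form
E[PCC within module] = a²/(a² + σ_noise²), used in parameter-recovery
tests. Defaults — 500 genes, 10 modules of 20 genes (background genes
belong to no module), 20 experiments of 5 samples, a = 1, σ_noise = 1
(within-module PCC ≈ 0.5), σ_batch = 0.5, baseline N(6, 1.5²) on the
log2 scale — describe a mid-sized, moderately noisy compendium with
clear but imperfect module structure.

Annotations mirror the modules: one term per module covering a `fidelity`
fraction of its genes, plus random decoy terms of matched sizes; at
fidelity 0 only decoys remain, so annotations are independent of the
expression structure. The shuffle null used by the evaluation re-assigns
gene labels by a permutation of the annotated universe, preserving every
term's size while destroying the module correspondence.

Platform pairs share the planted loading structure but draw independent
samples, factors, baselines and noise; a `divergence` parameter convexly
mixes the second platform's loading matrix with a gene-permuted copy
(0 = same structure, 1 = random with respect to the truth), which makes
cross-platform Jaccard reproducibility fall monotonically.

What the generator does **not** emulate: count-type noise
(negative-binomial mean–variance coupling, library-size variation),
probe-specific artifacts, correlated module overlap, or annotation-depth
bias toward highly expressed genes. Passing tests therefore demonstrate
the correctness and qualitative behavior of the estimators under a clean
latent-factor model, not their quantitative values on real compendia —
platform-level numbers (function scores, Jaccard coefficients, ComBat
and bagging effect sizes on real data) require the real corpora and are
out of scope here.

## Numerical choices and degenerate inputs

* Correlations are clipped to [−1, 1] post-`corrcoef`; matrices are
  validated symmetric to 1e-12 before ranking.
* Self-correlations are pinned to −∞ during ranking so non-self ranks run
  exactly 1..N−1; diagonals of rank/MR matrices are NaN.
* Rank ties use `scipy.stats.rankdata(method="average")`; row sums are
  preserved at N(N−1)/2.
* `logit`/`expit` come from `scipy.special`; the logit average runs in
  log space; all outputs constrained to (0, N).
* Zero-variance genes: dropped before correlation (with a logged list);
  passed through unchanged (as zeros) by the EB adjustment.
* Empty percentile bins emit NaN medians/quartiles rather than failing.
* TSV is the only matrix container: at the desk scale this package
  targets, a dense gene × gene TSV is adequate and diff-able, and the
  MR contract (exact agreement with the naive oracle) is independent of
  storage. Floating-point output is printed at 6 significant digits.

## Problem sizes

Test and acceptance runs use deliberately small instances chosen to make
every statistical property visible while keeping runs fast: networks of
50–500 genes, 6–24 experiments, bootstrap B = 20–30, 50 annotation
shuffles, 10,000 interval-coverage draws, 10 seeds for the bagging
comparison. These sizes are the package's own validation conditions; the
estimators themselves have no built-in size assumptions beyond dense
memory (≈ N² doubles per matrix).

## Known limitations

* The EB batch adjustment is a simplified one-step parametric scheme, not
  full ComBat (no iterative refinement, no nonparametric prior, no
  covariates); with heavily unbalanced designs the location prior can
  absorb real signal, which is why centering-only remains the default
  batch mode.
* The bootstrap treats experiments as exchangeable; systematic
  differences between experiment *types* (tissue panels vs. time
  courses) are not modeled.
* Probe selection assumes the reference network is itself reliable; with
  a poor reference it degrades toward arbitrary selection, which is why
  averaging is the fallback.
* The function score inherits the biases of the annotation source;
  unevenly annotated genomes overstate differences between platforms.
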