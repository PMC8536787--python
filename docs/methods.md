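# Methods

This note documents the statistical model, the defaults and why they
were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would want to know.

## Count model and reference fitting

UMI counts of a gene within one cell type are treated as negative
binomial with dispersion (size) λ and success probability p, so
μ = λp/(1−p) and σ² = λp/(1−p)² = μ/(1−p). Fitting is by maximum
likelihood on **raw** counts: library-size normalization would force all
cell types to the same total transcript content, which is false (e.g.
neurons carry several-fold more RNA than glia) and would bias the
estimated proportions, since the design matrix of the deconvolution
must preserve per-cell transcript totals.

The 2-D MLE is computed by profiling: for fixed λ the likelihood is
maximized exactly when the NB mean equals the sample mean, giving
p = x̄/(λ + x̄); the remaining 1-D problem in log λ is solved by bounded
scalar minimization on λ ∈ [1e−6, 1e6] (method-of-moments λ is used as a
sanity bracket). This is mathematically identical to joint bounded
optimization but faster and more robust. Degenerate branches:

* all-zero vector → flag `all_zero`, μ = σ² = 0 (such genes are dropped
  from the panel — a silent gene carries no compositional information);
* sample variance ≤ sample mean → flag `poisson_fallback`, σ² = μ. An
  interior NB fit does not exist for underdispersed data; the Poisson
  limit keeps the specificity weight finite and equal to 1;
* a fit collapsing to the p → 0 boundary is likewise demoted to the
  Poisson fallback.

Counts must be non-negative integers (tolerance 1e−8 for float input).

## Gene selection

**Markers** (default): one-vs-rest Wilcoxon rank-sum per cell type on
log1p counts-per-10k values — the large-sample normal approximation
with tie correction — BH-adjusted within each comparison; genes with
adjusted p < 0.01 are ranked by log2 fold change of the normalized
cluster mean over the rest mean and the top 200 per type retained.
Normalization is used only for this test, never for the NB fits. Genes
appearing in the top lists of more than 5 cell types are removed (they
mark identity poorly), as are mitochondrial genes (prefixes `mt-`,
`MT-`, `Mt-`, configurable). Output is sorted by gene id, so the
selection is deterministic.

**Balanced HVGs**: clusters are resampled to the median cluster size
(without replacement when larger, with replacement when smaller; the
seed fixes the draw), then genes are ranked by VST-standardized
variance: a lowess fit (frac 0.3) of log10 variance on log10 mean gives
each gene an expected standard deviation; standardized values are
clipped at √N and their variance is the score. Ties break by gene id.
The VST step is computed directly with statsmodels lowess.

## Gene weights

*Specificity* w^S = μ/σ² in the gene's most-expressing type (argmax over
the fitted means; ties take the lowest type index and are logged). For
NB fits w^S = 1 − p̂ ∈ (0, 1); for Poisson fallbacks w^S = 1.

*Stability* w^C = 1/VMR, where VMR is the variance-to-mean ratio of an
NB fit across samples; for an NB fit VMR = 1/(1 − p̂) ≥ 1. Sources of
samples, in order of preference: ≥ 3 replicate compound samples (per
replicate group when groups are given); ≥ 3 reference subjects, one
pseudo-bulk each (sum of raw UMIs over the subject's cells); otherwise
B = 20 bootstrap pseudo-samples, each pooling cells resampled with
replacement per type at the original cluster sizes. Poisson fallbacks
get VMR = w^C = 1; genes zero in every sample get w^C = 0 and are
excluded from the loss. w^C is clipped at 10 (the clip can only bind on
non-NB paths). Fewer than 3 samples cannot support a meaningful NB fit,
so the mode is refused rather than silently degraded.

## Platform-bias correction and the solver

For each replicate group (each sample is its own group when no groups
are given), the group's mean expression vector is regressed on the panel
means by NNLS and normalized to the simplex → coarse proportions τ.
The per-gene correction is r = log2(observed/predicted + 1): r = 1 at
ratio 1 (no correction), r = 0 when the observed count is zero, and
larger deviations get larger corrections. The +1 keeps the log finite
on zeros; the log compresses the heavy right tail of count ratios. Note
r also absorbs the overall library-size difference between the compound
sample and the per-cell reference scale. Genes whose predicted mean
under τ is zero are excluded from that group's loss (logged).

The weighted ridge loss is minimized over β ≥ 0 by L-BFGS-B with the
analytic gradient, initialized at τ scaled to the weighted least-squares
optimum along that direction. Convergence: ftol 1e−12 / gtol 1e−10, at
most 500 iterations; non-convergence is flagged on the result, never
silent. θ = β/Σβ; a fully zero β yields uniform θ with
`converged=False`.

The printed constraint β > 0 is implemented as the box bound β ≥ 0
(closure of the feasible set): exact zeros are legitimate answers for
absent cell types.

**Regularization default.** λ is data-driven: 1e−3 × (unregularized loss
at the initialization)/K, recomputed per sample. This keeps the penalty
a small dimensionless fraction of the data term, so the default
transfers across count scales; any float can be passed instead. The
penalty is a shrinkage diagnostic, not an identity: as λ grows,
estimates contract toward the ridge limit direction, which on typical
well-conditioned designs moves θ toward uniform (tested empirically on
a fixed instance), but that monotonicity is not a theorem.

## Synthetic data

The generator emulates the count structure the model assumes: per-type
gene means drawn lognormal (median 2, log-sd 1), disjoint marker blocks
(20% of genes split across types, 8-fold upweighted in their own type),
per-type total-transcript scales drawn from (1, 5) — real tissues show
up to order-of-magnitude spreads — NB dispersions from (2, 10), and
per-cell lognormal size factors (log-sd 0.1). Subjects receive
Dirichlet-weighted shares of each type (concentration 10), so donor
compositions differ realistically. Compound samples are sums of NB cell
draws allocated multinomially to types, with optional per-gene
lognormal platform bias exp(N(0, σ²)), σ = 0.3 in the benchmark
scenarios. Spatial spots follow the weighted-sum construction: 10 cells
per type sampled without replacement, weighted by the (normalized)
mixing proportions and summed — spot counts are therefore real-valued
and the deconvolver accepts non-negative reals.

What the generator does **not** emulate: ambient RNA, doublets, batch
effects within the reference, gene-length/GC effects, spatial
neighborhood structure, and cell types absent from the reference.
Passing tests therefore demonstrate correctness of the estimator under
its own model assumptions plus platform bias, not robustness to every
artifact of real tissue data.

Problem sizes in the test and acceptance runs were chosen to make the
statistical claims stable at interactive runtimes: the main benchmark
uses 8 types × 1000 genes × 300 cells/type with 50 compound samples of
500 cells; rare-cell detection uses 4 types and 100 spots; the
leave-one-out benchmark uses 5 subjects of a 5-type, 500-gene
reference.

## Evaluation conventions

mAD and RMSD are computed per sample over cell types; both the standard
rooted RMSD and the unrooted mean-squared variant are reported, since
both conventions circulate. Spearman uses average ranks for ties;
zero-variance vectors make correlations undefined and are reported as
NaN with a warning. ROC curves pool all (sample, type) presence calls
and sweep the detection threshold over every distinct estimate; AUC is
the trapezoid integral and equals the Mann–Whitney pair statistic
(property-tested exhaustively at small n). Detection of a rare type
requires its estimate to be **strictly** greater than the threshold
(default 0.5%). The leave-one-out harness rebuilds the panel and the
gene weights from the remaining subjects only, so no information from
the held-out subject leaks into the reference.

## Reference bundle

The fitted panel is a directory of TSVs plus `metadata.json`
(schema version, parameters, seeds, a SHA-256 of the source data).
Floats are written with 17 significant digits and parsed with
round-trip precision, so save → load → save is byte-identical, and
rebuilding from identical inputs and seed reproduces the bundle
byte-for-byte (metadata deliberately contains no timestamps).

## Known limitations

* Cell types missing from the reference are handled only implicitly:
  their transcripts inflate the proportions of the most similar
  reference types.
* The NB dispersion MLE is biased at very small sample counts (the
  cross-sample VMR from ~10 pseudo-samples underestimates the true VMR
  by roughly 20%); weights are relative, so this mostly cancels, but
  VMR values themselves should not be interpreted at small n.
* The marker rank-sum test uses the normal approximation, which is
  inaccurate for very small clusters (tens of cells are fine; single
  digits are not).
* Proportions are transcript-weighted only insofar as the raw-count
  design encodes per-type totals; absolute cell counts are out of scope.
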