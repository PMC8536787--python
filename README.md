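# nbdeconv

Cell-type deconvolution of compound RNA-seq — bulk libraries or spatial
transcriptomics spots — from an annotated single-cell reference.

## The problem

A bulk RNA-seq library or a spatial spot mixes transcripts from many
cells of different types. Given a single-cell reference with cell-type
annotations, `nbdeconv` estimates the fraction θ_k of each cell type k
in every compound sample. It is aimed at transcriptomics analysts who
have a clustered, annotated scRNA-seq atlas of a tissue and want to
decompose matched bulk samples or spatial spots — including cases where
the reference and the compound data come from different sequencing
platforms, and where cell types differ widely in total transcript
content or are closely related.

## The model

Raw UMI counts of gene *i* in cell type *k* are modelled as negative
binomial, X_ik ~ NB(λ_ik, p_ik), fitted per gene and type by maximum
likelihood on the **raw** counts (no library-size normalization — that
would erase genuine cell-type differences in transcript content). The
NB mean and variance are

    μ_ik = λ̂_ik p̂_ik / (1 − p̂_ik),    σ²_ik = λ̂_ik p̂_ik / (1 − p̂_ik)².

Two per-gene weights enter the fit:

* **specificity** w^S_i = μ_ik′ / σ²_ik′ where k′ is the gene's
  most-expressing type (for an NB fit this equals 1 − p̂, so w^S ∈ (0,1]);
* **stability** w^C_i = 1/VMR_i, the reciprocal cross-sample
  variance-to-mean ratio, estimated from replicate compound samples,
  per-subject pseudo-bulks of the reference, or bootstrap pseudo-samples.

A coarse NNLS pass gives provisional proportions τ, from which each gene
gets an adaptive platform-bias correction

    r_i = log2( y_i / Σ_k τ̂_k μ_ik + 1 ),

so genes deviating more from the coarse prediction are corrected more
(r = 1 means no correction). Final coefficients minimize the weighted,
L2-regularized loss

    L(β) = Σ_i w^C_i w^S_i ( y_i − r_i Σ_k β_k μ̂_ik )² + λ Σ_k β_k²,
    β_k ≥ 0,

by projected quasi-Newton (L-BFGS-B) with the analytic gradient, and
proportions are θ_k = β̂_k / Σ_k β̂_k.

A full synthetic-data layer (NB single-cell references with marker
blocks and per-type transcript-scale differences, pseudo-bulk synthesis,
weighted-sum spatial spots, rare-cell series, per-gene lognormal
platform bias) and an evaluation layer (mAD, RMSD, Pearson/Spearman,
presence-call ROC/AUC, detection rate, leave-one-subject-out
benchmarking) make the whole tool testable without any downloads.

## Worked example

```python
import numpy as np
from nbdeconv import (
    generate_synthetic_reference, build_reference, compute_cross_sample_weights,
    synthesize_compound, CompoundSampleSet, deconvolute, concordance_metrics,
)

# 1. synthetic single-cell reference: 6 cell types, 800 genes, known truth
ref, truth = generate_synthetic_reference(n_genes=800, n_types=6,
                                          cells_per_type=200, seed=0)

# 2. fit the NB reference panel (marker genes, raw UMI counts)
panel = build_reference(ref, gene_mode="markers")
print(f"panel: {panel.n_genes} genes x {panel.n_types} cell types")

# 3. gene stability weights via bootstrap pseudo-samples
w = compute_cross_sample_weights(ref, "bootstrap", B=20, seed=1)

# 4. a compound sample with known composition and per-gene platform bias
theta_true = np.array([0.30, 0.25, 0.20, 0.15, 0.07, 0.03])
y, mix, _ = synthesize_compound(truth, theta_true, n_cells=500,
                                bias_sigma=0.3, seed=2)

# 5. deconvolute and score
samples = CompoundSampleSet(counts=y[:, None], gene_ids=ref.gene_ids,
                            sample_ids=["bulk_1"])
res = deconvolute(samples, panel, weights=w)
m = concordance_metrics(res.theta[0], mix.theta0)
for ct, est, tru in zip(res.cell_types, res.theta[0], mix.theta0):
    print(f"{ct}  estimated={est:.3f}  true={tru:.3f}")
print(f"mAD={m.mad:.4f}  RMSD={m.rmsd:.4f}  Spearman={m.spearman:.3f}")
```

Output:

```
panel: 183 genes x 6 cell types
type00  estimated=0.286  true=0.306
type01  estimated=0.238  true=0.262
type02  estimated=0.275  true=0.200
type03  estimated=0.118  true=0.140
type04  estimated=0.062  true=0.064
type05  estimated=0.020  true=0.028
mAD=0.0250  RMSD=0.0344  Spearman=0.943
```

The estimate tracks the realized composition (the recorded truth differs
slightly from `theta_true` because the sample draws a finite number of
cells per type); mAD is the mean absolute error over the six
proportions, and the 3% minority type is recovered.

The same workflow is available from the shell:

```sh
nbdeconv simulate synth-ref --n-types 6 --seed 0 --out ref/
nbdeconv build-ref --counts ref/counts.tsv --annotations ref/annotations.tsv \
    --vmr bootstrap --out bundle/
nbdeconv deconv --ref bundle/ --mixture bulk.tsv --vmr-mode bootstrap --out est.tsv
nbdeconv eval --est est.tsv --truth truth.tsv --out eval/
```

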