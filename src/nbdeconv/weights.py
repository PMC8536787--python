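"""Cross-sample gene variability weights.

A gene that fluctuates strongly between comparable samples is a poor
witness of composition. Per gene, an NB fit across samples gives a
cross-sample mean and variance whose ratio (the variance-to-mean ratio,
VMR) measures that instability; its reciprocal w_C = 1/VMR down-weights
unstable genes in the deconvolution loss. Three sources of "samples" are
supported, depending on what the data offer:

* ``compound_replicates`` — the compound matrix itself has >= 3 replicate
  columns;
* ``reference_replicates`` — the single-cell reference has >= 3 subjects;
  one pseudo-sample per subject is formed by summing raw UMIs over all of
  that subject's cells;
* ``bootstrap`` — neither has replicates; B pseudo-samples are built by
  resampling cells with replacement per cell type at original cluster
  sizes and pooling.

For an NB fit VMR = 1/(1 - p_hat) >= 1, so w_C lies in (0, 1]; Poisson
fallbacks get VMR = w_C = 1, genes that are zero in every sample get
w_C = 0 and are excluded from the loss downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ValidationError
from .nbfit import FLAG_ALL_ZERO, FLAG_NB_OK, fit_nb_profile
from .reference import SingleCellReferenceData

logger = logging.getLogger(__name__)

MODE_COMPOUND = "compound_replicates"
MODE_REFERENCE = "reference_replicates"
MODE_BOOTSTRAP = "bootstrap"


@dataclass
class CrossSampleWeights:
    gene_ids: list[str]
    vmr: np.ndarray
    w_c: np.ndarray
    mode: str
    fit_flag: np.ndarray
    bootstrap_seed: int | None = None
    n_bootstrap: int | None = None

    def aligned_to(self, genes: list[str], default: float = 1.0) -> np.ndarray:
        """w_C re-indexed to ``genes``; genes without a weight get ``default``."""
        lut = dict(zip(self.gene_ids, self.w_c))
        missing = [g for g in genes if g not in lut]
        if missing:
            logger.warning(
                "%d panel genes missing from cross-sample weights; using %g",
                len(missing),
                default,
            )
        return np.array([lut.get(g, default) for g in genes])


def _pseudo_samples_from_subjects(ref: SingleCellReferenceData) -> np.ndarray:
    if ref.subject_labels is None:
        raise ConfigurationError("reference_replicates mode requires subject labels")
    subjects = sorted(set(map(str, ref.subject_labels)))
    if len(subjects) < 3:
        raise ConfigurationError(
            f"reference_replicates mode requires >= 3 subjects, found {len(subjects)}"
        )
    cols = [ref.counts[:, ref.subject_labels == s].sum(axis=1) for s in subjects]
    return np.column_stack(cols)


def _pseudo_samples_bootstrap(ref: SingleCellReferenceData, B: int, seed: int) -> np.ndarray:
    if B < 3:
        raise ConfigurationError(f"bootstrap mode requires B >= 3, got {B}")
    rng = np.random.default_rng(seed)
    cols = []
    for _ in range(B):
        total = np.zeros(ref.n_genes)
        for ct in ref.cell_types:
            idx = ref.cells_of_type(ct)
            take = rng.choice(idx, size=len(idx), replace=True)
            total += ref.counts[:, take].sum(axis=1)
        cols.append(total)
    return np.column_stack(cols)


def compute_cross_sample_weights(
    source,
    mode: str,
    *,
    gene_ids: list[str] | None = None,
    B: int = 20,
    seed: int = 0,
    ceiling: float = 10.0,
) -> CrossSampleWeights:
    """Per-gene VMR and stability weight w_C = 1/VMR under the given mode.

    ``source`` is a genes x samples count matrix for ``compound_replicates``
    (with ``gene_ids``), or a :class:`SingleCellReferenceData` for the
    reference-based modes.
    """
    if mode == MODE_COMPOUND:
        mat = np.asarray(source, dtype=float)
        if mat.ndim != 2:
            raise ValidationError("compound sample matrix must be 2-D (genes x samples)")
        if mat.shape[1] < 3:
            raise ConfigurationError(
                f"compound_replicates mode requires >= 3 samples, found {mat.shape[1]}"
            )
        if gene_ids is None or len(gene_ids) != mat.shape[0]:
            raise ValidationError("gene_ids must be provided and match the matrix rows")
        if not np.allclose(mat, np.rint(mat)):
            logger.warning("non-integral compound counts rounded for the NB fit")
            mat = np.rint(mat)
        genes = list(gene_ids)
        bs_seed = bs_B = None
    elif mode == MODE_REFERENCE:
        mat = _pseudo_samples_from_subjects(source)
        genes = list(source.gene_ids)
        bs_seed = bs_B = None
    elif mode == MODE_BOOTSTRAP:
        mat = _pseudo_samples_bootstrap(source, B, seed)
        genes = list(source.gene_ids)
        bs_seed, bs_B = seed, B
    else:
        raise ConfigurationError(f"unknown cross-sample mode {mode!r}")

    I = mat.shape[0]
    vmr = np.zeros(I)
    w_c = np.zeros(I)
    flags = np.empty(I, dtype=object)
    for i in range(I):
        f = fit_nb_profile(mat[i])
        flags[i] = f.flag
        if f.flag == FLAG_ALL_ZERO:
            vmr[i], w_c[i] = 0.0, 0.0
        elif f.flag == FLAG_NB_OK:
            vmr[i] = f.var / f.mu  # = 1/(1 - p_hat)
            w_c[i] = 1.0 / vmr[i]
        else:
            vmr[i], w_c[i] = 1.0, 1.0
    np.minimum(w_c, ceiling, out=w_c)
    return CrossSampleWeights(
        gene_ids=genes,
        vmr=vmr,
        w_c=w_c,
        mode=mode,
        fit_flag=flags,
        bootstrap_seed=bs_seed,
        n_bootstrap=bs_B,
    )
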