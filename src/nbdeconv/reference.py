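"""Single-cell reference handling: gene selection and NB profile fitting.

The reference is a raw-UMI genes x cells matrix with a cell-type label per
cell (optionally a subject label). Two gene-selection paths are offered:

* one-vs-rest marker genes (tie-corrected Wilcoxon rank-sum on log1p
  counts-per-10k values, BH-adjusted, ranked by log2 fold change of the
  normalized cluster mean against the rest), and
* balanced highly variable genes (clusters resampled to the median cluster
  size, then a variance-stabilizing-transform standardized variance).

Normalization is used for *testing/ranking only*: the NB profiles that
form the deconvolution design matrix are always fitted on raw UMI counts,
so cell-type differences in total transcript content are preserved.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, ValidationError
from .nbfit import FLAG_ALL_ZERO, FLAG_NB_OK, fit_nb_profile

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"
DEFAULT_MITO_PREFIXES = ("mt-", "MT-", "Mt-")


@dataclass
class SingleCellReferenceData:
    """Annotated raw-UMI single-cell reference (genes x cells)."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_type_labels: np.ndarray
    subject_labels: np.ndarray | None = None
    min_cells_per_type: int = 10

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.cell_type_labels = np.asarray(self.cell_type_labels, dtype=object)
        if self.subject_labels is not None:
            self.subject_labels = np.asarray(self.subject_labels, dtype=object)
        self.validate()

    def validate(self) -> None:
        I, N = self.counts.shape
        if len(self.gene_ids) != I:
            raise ValidationError("gene_ids length does not match counts rows")
        if len(set(self.gene_ids)) != I:
            raise ValidationError("gene_ids are not unique")
        if len(self.cell_ids) != N or len(self.cell_type_labels) != N:
            raise ValidationError("cell annotations do not match counts columns")
        if self.subject_labels is not None and len(self.subject_labels) != N:
            raise ValidationError("subject_labels length does not match counts columns")
        if np.any(self.counts < 0) or not np.allclose(self.counts, np.rint(self.counts)):
            raise ValidationError("reference counts must be non-negative integers")
        for ct, n in zip(*np.unique(self.cell_type_labels, return_counts=True)):
            if n < self.min_cells_per_type:
                raise ValidationError(
                    f"cell type {ct!r} has {n} cells, fewer than the minimum "
                    f"{self.min_cells_per_type}"
                )

    @property
    def cell_types(self) -> list[str]:
        return sorted(set(map(str, self.cell_type_labels)))

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def cells_of_type(self, cell_type: str) -> np.ndarray:
        return np.flatnonzero(self.cell_type_labels == cell_type)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.counts).tobytes())
        h.update("\n".join(self.gene_ids).encode())
        h.update("\n".join(map(str, self.cell_type_labels)).encode())
        if self.subject_labels is not None:
            h.update("\n".join(map(str, self.subject_labels)).encode())
        return h.hexdigest()


@dataclass
class ReferencePanel:
    """Fitted per-gene / per-cell-type NB reference profiles.

    ``mu``/``var``/``dispersion``/``success_prob`` are I x K matrices over
    ``selected_genes`` x ``cell_types``; ``specificity_weight`` is the
    mean-to-variance ratio of each gene in its most-expressing type.
    """

    selected_genes: list[str]
    cell_types: list[str]
    mu: np.ndarray
    var: np.ndarray
    dispersion: np.ndarray
    success_prob: np.ndarray
    specificity_weight: np.ndarray
    fit_flag: np.ndarray
    gene_mode: str
    metadata: dict = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return len(self.selected_genes)

    @property
    def n_types(self) -> int:
        return len(self.cell_types)

    def validate(self, atol: float = 1e-6) -> None:
        I, K = self.mu.shape
        if (
            len(self.selected_genes) != I
            or len(self.cell_types) != K
            or self.var.shape != (I, K)
            or self.dispersion.shape != (I, K)
            or self.success_prob.shape != (I, K)
            or self.fit_flag.shape != (I, K)
            or self.specificity_weight.shape != (I,)
        ):
            raise ValidationError("reference panel shapes are inconsistent")
        ok = self.fit_flag == FLAG_NB_OK
        if np.any(self.var[ok] <= self.mu[ok]):
            raise ValidationError("nb_ok entries must be overdispersed (var > mu)")
        lam, p = self.dispersion[ok], self.success_prob[ok]
        if not np.allclose(self.mu[ok], lam * p / (1 - p), rtol=atol, atol=atol):
            raise ValidationError("nb_ok entries violate mu = lambda*p/(1-p)")
        zero = self.fit_flag == FLAG_ALL_ZERO
        if np.any(self.mu[zero] != 0) or np.any(self.var[zero] != 0):
            raise ValidationError("all_zero entries must have mu = var = 0")
        if np.any(self.specificity_weight <= 0) or np.any(self.specificity_weight > 1 + atol):
            raise ValidationError("specificity weights must lie in (0, 1]")


def _cp10k(counts: np.ndarray) -> np.ndarray:
    lib = counts.sum(axis=0)
    lib = np.where(lib > 0, lib, 1.0)
    return counts / lib * 1e4


def _tie_term(row: np.ndarray) -> float:
    # sum of t^3 - t over runs of tied values
    _, t = np.unique(row, return_counts=True)
    return float(np.sum(t.astype(float) ** 3 - t))


def _is_mito(gene: str, prefixes: tuple[str, ...]) -> bool:
    return any(gene.startswith(p) for p in prefixes)


def select_marker_genes(
    ref: SingleCellReferenceData,
    top_n: int = 200,
    p_cutoff: float = 0.01,
    max_types: int = 5,
    mito_prefixes: tuple[str, ...] = DEFAULT_MITO_PREFIXES,
) -> list[str]:
    """One-vs-rest marker selection.

    For each cell type, genes with BH-adjusted rank-sum p < ``p_cutoff``
    are ranked by log2 fold change of the normalized cluster mean over the
    rest mean, and the top ``top_n`` retained. The union over types is
    returned after removing genes marking more than ``max_types`` types
    and mitochondrial genes. Output is sorted by gene id.
    """
    types = ref.cell_types
    if len(types) < 2:
        raise ConfigurationError("marker selection requires at least 2 cell types")

    norm = _cp10k(ref.counts)
    logn = np.log1p(norm)
    N = logn.shape[1]

    ranks = rankdata(logn, axis=1)
    tie = np.fromiter((_tie_term(row) for row in logn), dtype=float, count=logn.shape[0])

    membership: dict[str, set[str]] = {g: set() for g in ref.gene_ids}
    for ct in types:
        mask = ref.cell_type_labels == ct
        n1 = int(mask.sum())
        n2 = N - n1
        rsum = ranks[:, mask].sum(axis=1)
        mean_r = n1 * (N + 1) / 2.0
        var_r = n1 * n2 / 12.0 * ((N + 1) - tie / (N * (N - 1)))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(var_r > 0, (rsum - mean_r) / np.sqrt(var_r), 0.0)
        pvals = 2.0 * (1.0 - ndtr(np.abs(z)))
        padj = multipletests(pvals, method="fdr_bh")[1]

        mean_in = norm[:, mask].mean(axis=1)
        mean_out = norm[:, ~mask].mean(axis=1)
        lfc = np.log2((mean_in + 1e-9) / (mean_out + 1e-9))

        cand = np.flatnonzero((padj < p_cutoff) & (lfc > 0))
        order = cand[np.argsort(-lfc[cand], kind="stable")][:top_n]
        for gi in order:
            membership[ref.gene_ids[gi]].add(ct)

    selected = [
        g
        for g, cts in membership.items()
        if 0 < len(cts) <= max_types and not _is_mito(g, mito_prefixes)
    ]
    if not selected:
        raise ValidationError("no informative genes survived marker selection")
    return sorted(selected)


def select_balanced_hvgs(
    ref: SingleCellReferenceData,
    n_top: int = 2000,
    seed: int = 0,
    mito_prefixes: tuple[str, ...] = DEFAULT_MITO_PREFIXES,
    lowess_frac: float = 0.3,
) -> list[str]:
    """Highly variable genes on a cluster-balanced matrix.

    Each cluster is resampled to the median cluster size (without
    replacement when larger, with replacement when smaller), then the
    VST-standardized variance (lowess fit of log10 variance on log10 mean,
    standardized values clipped at sqrt(N)) ranks the genes.
    """
    rng = np.random.default_rng(seed)
    sizes = [len(ref.cells_of_type(ct)) for ct in ref.cell_types]
    target = int(np.median(sizes))

    cols: list[np.ndarray] = []
    for ct in ref.cell_types:
        idx = ref.cells_of_type(ct)
        cols.append(rng.choice(idx, size=target, replace=len(idx) < target))
    balanced = ref.counts[:, np.concatenate(cols)]
    n_cells = balanced.shape[1]

    mean = balanced.mean(axis=1)
    var = balanced.var(axis=1, ddof=1)
    score = np.zeros(ref.n_genes)
    ok = (mean > 0) & (var > 0)
    if ok.any():
        fitted = lowess(
            np.log10(var[ok]), np.log10(mean[ok]), frac=lowess_frac, return_sorted=False
        )
        sd_exp = np.sqrt(np.power(10.0, fitted))
        z = (balanced[ok] - mean[ok, None]) / sd_exp[:, None]
        np.clip(z, -np.sqrt(n_cells), np.sqrt(n_cells), out=z)
        score[ok] = z.var(axis=1, ddof=1)

    keep = [i for i, g in enumerate(ref.gene_ids) if not _is_mito(g, mito_prefixes)]
    if n_top > len(keep):
        logger.warning("n_top=%d exceeds available gene count %d; capping", n_top, len(keep))
        n_top = len(keep)
    keep_arr = np.array(keep)
    # descending score, gene id as deterministic tie-break
    order = sorted(keep_arr, key=lambda i: (-score[i], ref.gene_ids[i]))
    return [ref.gene_ids[i] for i in order[:n_top]]


def compute_specificity_weights(panel: ReferencePanel) -> np.ndarray:
    """Specificity weight w_S per gene: mean/variance in the most-expressing type.

    For nb_ok fits this equals 1 - p_hat (hence lies in (0, 1]); Poisson
    fallbacks give exactly 1. Genes whose most-expressing type is all_zero
    (i.e. the gene is silent everywhere) get weight 0 and a warning; the
    builder drops them.
    """
    kprime = np.argmax(panel.mu, axis=1)  # ties -> lowest type index
    n_tied = np.sum(np.sum(panel.mu == panel.mu.max(axis=1, keepdims=True), axis=1) > 1)
    if n_tied:
        logger.info("%d genes had tied argmax cell types; lowest index used", n_tied)
    rows = np.arange(panel.n_genes)
    mu_best = panel.mu[rows, kprime]
    var_best = panel.var[rows, kprime]
    w = np.zeros(panel.n_genes)
    pos = var_best > 0
    w[pos] = mu_best[pos] / var_best[pos]
    if np.any(~pos):
        warnings.warn(
            f"{int(np.sum(~pos))} selected genes are silent in every cell type "
            "and will be dropped",
            stacklevel=2,
        )
    return w


def fit_panel_profiles(
    ref: SingleCellReferenceData, genes: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit NB profiles for every (gene, cell type) pair on raw UMI counts."""
    gene_index = {g: i for i, g in enumerate(ref.gene_ids)}
    missing = [g for g in genes if g not in gene_index]
    if missing:
        raise ValidationError(f"genes not present in reference: {missing[:10]}")
    rows = [gene_index[g] for g in genes]
    types = ref.cell_types
    I, K = len(genes), len(types)
    mu = np.zeros((I, K))
    var = np.zeros((I, K))
    lam = np.zeros((I, K))
    p = np.zeros((I, K))
    flag = np.empty((I, K), dtype=object)
    type_cols = [ref.cells_of_type(ct) for ct in types]
    for j, cols in enumerate(type_cols):
        block = ref.counts[np.ix_(rows, cols)]
        for i in range(I):
            f = fit_nb_profile(block[i])
            mu[i, j], var[i, j] = f.mu, f.var
            lam[i, j], p[i, j] = f.lambda_, f.p
            flag[i, j] = f.flag
    return mu, var, lam, p, flag


def build_reference(
    ref: SingleCellReferenceData,
    gene_mode: str = "markers",
    *,
    seed: int = 0,
    top_n: int = 200,
    p_cutoff: float = 0.01,
    max_types: int = 5,
    n_top_hvg: int = 2000,
    mito_prefixes: tuple[str, ...] = DEFAULT_MITO_PREFIXES,
) -> ReferencePanel:
    """Select genes, fit NB profiles and specificity weights; return the panel.

    Deterministic given inputs and ``seed``; invariant to the ordering of
    cells within a type (fits depend only on each type's multiset of
    counts).
    """
    if gene_mode == "markers":
        genes = select_marker_genes(
            ref, top_n=top_n, p_cutoff=p_cutoff, max_types=max_types, mito_prefixes=mito_prefixes
        )
    elif gene_mode == "hvg":
        genes = select_balanced_hvgs(ref, n_top=n_top_hvg, seed=seed, mito_prefixes=mito_prefixes)
    else:
        raise ConfigurationError(f"unknown gene_mode {gene_mode!r}")

    mu, var, lam, p, flag = fit_panel_profiles(ref, genes)
    panel = ReferencePanel(
        selected_genes=list(genes),
        cell_types=ref.cell_types,
        mu=mu,
        var=var,
        dispersion=lam,
        success_prob=p,
        specificity_weight=np.ones(len(genes)),
        fit_flag=flag,
        gene_mode=gene_mode,
        metadata={
            "schema_version": SCHEMA_VERSION,
            "gene_mode": gene_mode,
            "seed": seed,
            "params": {
                "top_n": top_n,
                "p_cutoff": p_cutoff,
                "max_types": max_types,
                "n_top_hvg": n_top_hvg,
                "mito_prefixes": list(mito_prefixes),
            },
            "source_hash": ref.content_hash(),
        },
    )
    w = compute_specificity_weights(panel)
    keep = w > 0
    panel = ReferencePanel(
        selected_genes=[g for g, k in zip(panel.selected_genes, keep) if k],
        cell_types=panel.cell_types,
        mu=mu[keep],
        var=var[keep],
        dispersion=lam[keep],
        success_prob=p[keep],
        specificity_weight=w[keep],
        fit_flag=flag[keep],
        gene_mode=gene_mode,
        metadata=panel.metadata,
    )
    panel.validate()
    return panel
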