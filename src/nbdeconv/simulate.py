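"""Synthetic data generation: the test bed for the whole tool.

Three layers:

* pseudo-bulk synthesis from an annotated single-cell reference (sum of
  raw UMIs over a subject's cells; truth = cell-count fractions);
* spatial-spot simulation (10 cells sampled without replacement per cell
  type, weighted by the mixing proportions and summed — spot counts are
  therefore real-valued);
* fully synthetic single-cell references with known per-(gene, type) NB
  parameters, disjoint marker blocks, cell-type-level differences in
  total transcript content, and per-cell lognormal size factors —
  emulating the count structure of droplet scRNA-seq that the method
  assumes.

Per-gene multiplicative platform bias (lognormal) can be injected into
any compound vector to exercise the adaptive correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .reference import SingleCellReferenceData

_TRUTH_TOL = 1e-12


@dataclass
class MixingTruth:
    """Ground-truth composition of one synthesized compound sample."""

    theta0: np.ndarray
    cell_types: list[str]
    provenance: str  # "cell_counts" | "scheme"
    scheme_id: str | None = None
    seed: int | None = None
    proportions_as_given: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta0 = np.asarray(self.theta0, dtype=float)
        if abs(self.theta0.sum() - 1.0) > _TRUTH_TOL:
            raise ValidationError("mixing truth must sum to 1")
        if np.any(self.theta0 < 0):
            raise ValidationError("mixing truth must be non-negative")


@dataclass
class SyntheticTruth:
    """Generator-recorded ground truth for a synthetic reference."""

    gene_ids: list[str]
    cell_types: list[str]
    mu: np.ndarray  # genes x types per-cell NB means (incl. type scale)
    dispersion: np.ndarray  # genes x types NB size parameters
    marker_blocks: dict[str, list[str]]
    type_scales: np.ndarray
    cell_size_sigma: float
    seed: int
    params: dict = field(default_factory=dict)


def synthesize_bulk(
    ref: SingleCellReferenceData, subject, cell_types: list[str] | None = None
) -> tuple[np.ndarray, MixingTruth]:
    """Pseudo-bulk for one subject: per-gene sum of raw UMIs over its cells.

    ``cell_types`` restricts the pool (types outside it are excluded and
    get exact truth 0); by default all of the subject's cells are summed.
    The output total equals the included cells' total UMIs exactly.
    """
    if ref.subject_labels is None:
        raise ValidationError("reference has no subject labels")
    mask = ref.subject_labels == subject
    if not mask.any():
        raise ValidationError(f"unknown subject {subject!r}")
    types = ref.cell_types
    if cell_types is not None:
        unknown = set(cell_types) - set(types)
        if unknown:
            raise ValidationError(f"unknown cell types: {sorted(unknown)}")
        mask = mask & np.isin(ref.cell_type_labels, list(cell_types))
        if not mask.any():
            raise ValidationError(f"subject {subject!r} has no cells of the requested types")
    counts_per_type = np.array(
        [int(np.sum(mask & (ref.cell_type_labels == ct))) for ct in types], dtype=float
    )
    y = ref.counts[:, mask].sum(axis=1)
    truth = MixingTruth(
        theta0=counts_per_type / counts_per_type.sum(),
        cell_types=types,
        provenance="cell_counts",
    )
    return y, truth


def simulate_spot(
    ref: SingleCellReferenceData,
    proportions,
    n_cells_per_type: int = 10,
    seed: int = 0,
    scheme_id: str | None = None,
) -> tuple[np.ndarray, MixingTruth]:
    """One spatial spot: weighted sum of cells sampled without replacement.

    ``proportions`` is a mapping cell type -> weight or a vector over
    ``ref.cell_types``; weights are normalized to sum 1 (so printed
    schemes like 0.33:0.33:0.33 are valid input) and recorded both ways.
    """
    types = ref.cell_types
    if isinstance(proportions, dict):
        unknown = set(proportions) - set(types)
        if unknown:
            raise ValidationError(f"unknown cell types: {sorted(unknown)}")
        p_given = np.array([float(proportions.get(ct, 0.0)) for ct in types])
    else:
        p_given = np.asarray(proportions, dtype=float)
        if p_given.shape != (len(types),):
            raise ValidationError("proportions vector must align with ref.cell_types")
    if np.any(p_given < 0) or p_given.sum() <= 0:
        raise ValidationError("proportions must be non-negative with a positive sum")
    p = p_given / p_given.sum()

    rng = np.random.default_rng(seed)
    y = np.zeros(ref.n_genes)
    for k, ct in enumerate(types):
        if p[k] == 0:
            continue
        idx = ref.cells_of_type(ct)
        if len(idx) < n_cells_per_type:
            raise ValidationError(
                f"cell type {ct!r} has {len(idx)} cells, fewer than "
                f"n_cells_per_type={n_cells_per_type}"
            )
        take = rng.choice(idx, size=n_cells_per_type, replace=False)
        y += p[k] * ref.counts[:, take].sum(axis=1)
    truth = MixingTruth(
        theta0=p,
        cell_types=types,
        provenance="scheme",
        scheme_id=scheme_id,
        seed=seed,
        proportions_as_given=p_given,
    )
    return y, truth


def rare_cell_series(
    ref: SingleCellReferenceData,
    rare_type: str,
    companion_types: list[str],
    fractions=None,
    n_reps: int = 100,
    seed: int = 0,
    n_cells_per_type: int = 10,
) -> list[tuple[np.ndarray, MixingTruth]]:
    """Spots with the rare type at each fraction f, companions splitting 1-f evenly."""
    if fractions is None:
        fractions = np.round(np.arange(0.01, 0.1001, 0.01), 10)
    types = set(ref.cell_types)
    for ct in [rare_type, *companion_types]:
        if ct not in types:
            raise ValidationError(f"unknown cell type {ct!r}")
    rng = np.random.default_rng(seed)
    out = []
    for f in fractions:
        share = (1.0 - f) / len(companion_types)
        scheme = {rare_type: float(f), **{ct: share for ct in companion_types}}
        for _ in range(n_reps):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            out.append(
                simulate_spot(
                    ref,
                    scheme,
                    n_cells_per_type=n_cells_per_type,
                    seed=sub_seed,
                    scheme_id=f"rare_{f:g}",
                )
            )
    return out


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: np.ndarray) -> np.ndarray:
    # numpy parametrization: n = size, p = n / (n + mean)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def generate_synthetic_reference(
    n_genes: int = 1000,
    n_types: int = 8,
    cells_per_type: int = 300,
    marker_frac: float = 0.2,
    marker_fold: float = 8.0,
    type_scale_range: tuple[float, float] = (1.0, 5.0),
    dispersion_range: tuple[float, float] = (2.0, 10.0),
    cell_size_sigma: float = 0.1,
    n_subjects: int = 1,
    seed: int = 0,
    base_mean_log: float = np.log(2.0),
    base_mean_sigma: float = 1.0,
) -> tuple[SingleCellReferenceData, SyntheticTruth]:
    """Synthetic single-cell reference with recorded NB ground truth.

    Genes get a lognormal baseline mean; the first ``marker_frac`` of the
    genome is split into disjoint per-type marker blocks whose means are
    multiplied by ``marker_fold`` in their own type. Each type carries a
    total-transcript scale factor from ``type_scale_range`` (real tissues
    show order-of-magnitude differences between, e.g., neurons and immune
    cells). Counts are NB draws with per-cell lognormal size factors.
    """
    if not (0 < marker_frac < 1):
        raise ValidationError("marker_frac must be in (0, 1)")
    if min(n_genes, n_types, cells_per_type, n_subjects) <= 0 or marker_fold <= 0:
        raise ValidationError("generator parameters must be positive")
    rng = np.random.default_rng(seed)

    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    cell_types = [f"type{k:02d}" for k in range(n_types)]

    base = rng.lognormal(mean=base_mean_log, sigma=base_mean_sigma, size=n_genes)
    mu = np.tile(base[:, None], (1, n_types))
    n_marker = int(marker_frac * n_genes)
    block = max(n_marker // n_types, 1)
    marker_blocks: dict[str, list[str]] = {}
    for k, ct in enumerate(cell_types):
        lo, hi = k * block, min((k + 1) * block, n_marker)
        marker_blocks[ct] = gene_ids[lo:hi]
        mu[lo:hi, k] *= marker_fold

    scales = rng.uniform(*type_scale_range, size=n_types)
    mu = mu * scales[None, :]
    disp = rng.uniform(*dispersion_range, size=(n_genes, n_types))

    counts_blocks = []
    labels = []
    for k in range(n_types):
        size_factors = rng.lognormal(mean=0.0, sigma=cell_size_sigma, size=cells_per_type)
        mean_mat = mu[:, k : k + 1] * size_factors[None, :]
        counts_blocks.append(_nb_draw(rng, mean_mat, np.tile(disp[:, k : k + 1], (1, cells_per_type))))
        labels.extend([cell_types[k]] * cells_per_type)
    counts = np.concatenate(counts_blocks, axis=1).astype(float)

    n_cells = counts.shape[1]
    cell_ids = [f"cell{c:06d}" for c in range(n_cells)]
    # subjects receive Dirichlet-weighted shares of each type, so subject
    # compositions differ (as real donors do) while every subject keeps
    # cells of every type
    subject_names = [f"subject{s}" for s in range(n_subjects)]
    subjects = np.empty(n_cells, dtype=object)
    for k in range(n_types):
        sl = slice(k * cells_per_type, (k + 1) * cells_per_type)
        if n_subjects == 1:
            subjects[sl] = subject_names[0]
        else:
            shares = rng.dirichlet(np.full(n_subjects, 10.0))
            alloc = rng.multinomial(cells_per_type - n_subjects, shares) + 1
            subjects[sl] = rng.permutation(np.repeat(subject_names, alloc))

    ref = SingleCellReferenceData(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cell_type_labels=np.array(labels, dtype=object),
        subject_labels=subjects if n_subjects > 1 else None,
        min_cells_per_type=min(10, cells_per_type),
    )
    truth = SyntheticTruth(
        gene_ids=gene_ids,
        cell_types=cell_types,
        mu=mu,
        dispersion=disp,
        marker_blocks=marker_blocks,
        type_scales=scales,
        cell_size_sigma=cell_size_sigma,
        seed=seed,
        params={
            "n_genes": n_genes,
            "n_types": n_types,
            "cells_per_type": cells_per_type,
            "marker_frac": marker_frac,
            "marker_fold": marker_fold,
            "type_scale_range": list(type_scale_range),
            "dispersion_range": list(dispersion_range),
            "n_subjects": n_subjects,
        },
    )
    return ref, truth


def synthesize_compound(
    truth: SyntheticTruth,
    theta: np.ndarray,
    n_cells: int = 500,
    bias_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, MixingTruth, np.ndarray]:
    """A compound sample from a synthetic truth: NB cell draws + platform bias.

    ``n_cells`` cells are allocated to types by a multinomial draw on
    ``theta`` (the realized cell counts define the recorded truth), each
    cell's counts drawn NB from its type's (mu, dispersion), summed, then
    per-gene lognormal platform bias applied. Returns (counts, truth,
    bias multipliers).
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (len(truth.cell_types),) or np.any(theta < 0) or theta.sum() <= 0:
        raise ValidationError("theta must be a non-negative vector over the truth's cell types")
    theta = theta / theta.sum()
    rng = np.random.default_rng(seed)
    alloc = rng.multinomial(n_cells, theta)
    y = np.zeros(len(truth.gene_ids))
    for k, nk in enumerate(alloc):
        if nk == 0:
            continue
        mean_mat = np.tile(truth.mu[:, k : k + 1], (1, nk))
        disp_mat = np.tile(truth.dispersion[:, k : k + 1], (1, nk))
        y += _nb_draw(rng, mean_mat, disp_mat).sum(axis=1)
    y, mult = inject_platform_bias(y, bias_sigma, seed=int(rng.integers(0, 2**31 - 1)))
    mix = MixingTruth(
        theta0=alloc / alloc.sum(),
        cell_types=list(truth.cell_types),
        provenance="cell_counts",
        seed=seed,
    )
    return y, mix, mult


def inject_platform_bias(
    counts: np.ndarray, bias_sigma: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Apply per-gene multiplicative lognormal platform bias exp(N(0, sigma^2))."""
    if bias_sigma < 0:
        raise ValidationError("bias_sigma must be >= 0")
    counts = np.asarray(counts, dtype=float)
    if bias_sigma == 0:
        return counts.copy(), np.ones_like(counts)
    rng = np.random.default_rng(seed)
    mult = rng.lognormal(mean=0.0, sigma=bias_sigma, size=counts.shape)
    return counts * mult, mult
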