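"""Cell-type proportion estimation for compound samples.

Each compound sample (bulk library or spatial spot) is approximated as a
non-negative combination of the panel's per-type mean profiles,

    y_i  ~=  r_i * sum_k beta_k * mu_ik ,    beta_k >= 0,

where r_i is a per-gene platform-bias correction learned adaptively: a
coarse NNLS pass gives provisional proportions tau, and

    r_i = log2( y_i / sum_k tau_k mu_ik  +  1 )

so genes deviating more from the coarse prediction receive a larger
correction (r = 1 means none). The betas minimize a weighted, L2-
regularized sum of squares with per-gene weights w_C * w_S, solved by
box-constrained quasi-Newton (L-BFGS-B) with the analytic gradient, and
are rescaled to proportions theta = beta / sum(beta).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, nnls

from .errors import DegenerateInputError, ValidationError
from .reference import ReferencePanel
from .weights import CrossSampleWeights

logger = logging.getLogger(__name__)

_SIMPLEX_TOL = 1e-9


@dataclass
class CompoundSampleSet:
    """Genes x samples matrix of raw compound counts to deconvolute.

    Real-valued entries are permitted (simulated spots are weighted sums
    of cells). ``replicate_groups`` maps sample id -> group label; samples
    of a group share the coarse estimate and correction factors.
    """

    counts: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    replicate_groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValidationError("compound counts must be 2-D (genes x samples)")
        if np.any(self.counts < 0):
            raise ValidationError("compound counts must be non-negative")
        if len(self.gene_ids) != self.counts.shape[0]:
            raise ValidationError("gene_ids length does not match counts rows")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids in compound sample set")
        if len(self.sample_ids) != self.counts.shape[1]:
            raise ValidationError("sample_ids length does not match counts columns")
        if self.replicate_groups is not None:
            unknown = set(self.replicate_groups) - set(self.sample_ids)
            if unknown:
                raise ValidationError(f"replicate_groups references unknown samples: {sorted(unknown)[:5]}")

    def group_of(self, sample_id: str) -> str:
        if self.replicate_groups is None:
            return sample_id
        return self.replicate_groups.get(sample_id, sample_id)


@dataclass
class DeconvolutionResult:
    sample_ids: list[str]
    cell_types: list[str]
    theta: np.ndarray
    beta_raw: np.ndarray
    tau_coarse: np.ndarray
    lambda_used: np.ndarray
    loss_value: np.ndarray
    n_iter: np.ndarray
    converged: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    correction_factors: dict[str, np.ndarray] = field(default_factory=dict)
    correction_mask: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.theta, index=self.sample_ids, columns=self.cell_types)
        df.index.name = "sample_id"
        df["converged"] = self.converged
        df["loss"] = self.loss_value
        return df


def coarse_estimate(mu_compound: np.ndarray, panel: ReferencePanel) -> np.ndarray:
    """First-pass proportions: NNLS of the compound mean on the panel means.

    Coefficients are normalized to the simplex (the scale constant of the
    regression is absorbed by the normalization). An all-zero NNLS
    solution yields uniform proportions with a warning.
    """
    y = np.asarray(mu_compound, dtype=float)
    if y.shape != (panel.n_genes,):
        raise ValidationError("mu_compound must align with the panel's selected genes")
    if not np.any(y > 0):
        raise DegenerateInputError("compound mean expression is identically zero")
    coef, _ = nnls(panel.mu, y)
    total = coef.sum()
    if total <= 0:
        warnings.warn("coarse NNLS returned the zero solution; using uniform proportions", stacklevel=2)
        return np.full(panel.n_types, 1.0 / panel.n_types)
    return coef / total


def compute_correction_factors(
    mu_compound: np.ndarray, panel: ReferencePanel, tau: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene platform-bias corrections r_i = log2(observed/predicted + 1).

    Returns ``(r, valid)``; genes whose predicted mean under tau is zero
    cannot be corrected and are masked out (``valid`` False).
    """
    tau = np.asarray(tau, dtype=float)
    if not (np.all(tau >= 0) and abs(tau.sum() - 1.0) < 1e-6):
        raise ValidationError("tau must lie on the probability simplex")
    pred = panel.mu @ tau
    valid = pred > 0
    if not np.all(valid):
        logger.info("%d genes have zero predicted mean under tau and are excluded", int(np.sum(~valid)))
    r = np.zeros_like(pred)
    r[valid] = np.log2(mu_compound[valid] / pred[valid] + 1.0)
    return r, valid


def loss_and_gradient(
    beta: np.ndarray,
    y: np.ndarray,
    mu: np.ndarray,
    w: np.ndarray,
    r: np.ndarray,
    lam: float,
) -> tuple[float, np.ndarray]:
    """Weighted regularized squared loss and its analytic gradient.

    loss = sum_i w_i (y_i - r_i sum_k beta_k mu_ik)^2 + lam * sum_k beta_k^2
    G_k  = -2 sum_i r_i mu_ik w_i (y_i - r_i sum_k beta_k mu_ik) + 2 lam beta_k
    """
    beta = np.asarray(beta, dtype=float)
    I, K = mu.shape
    if beta.shape != (K,) or y.shape != (I,) or w.shape != (I,) or r.shape != (I,):
        raise ValidationError("loss_and_gradient: dimension mismatch")
    resid = y - r * (mu @ beta)
    loss = float(w @ resid**2) + lam * float(beta @ beta)
    grad = -2.0 * (mu.T @ (r * w * resid)) + 2.0 * lam * beta
    return loss, grad


def _auto_lambda(beta0, y, mu, w, r, scale: float = 1e-3) -> float:
    """Scale-free default regularization: a small fraction of the data loss
    at the coarse solution, per cell type."""
    l0, _ = loss_and_gradient(beta0, y, mu, w, r, 0.0)
    return scale * l0 / mu.shape[1]


def _solve_single(
    y: np.ndarray,
    mu: np.ndarray,
    w: np.ndarray,
    r: np.ndarray,
    lam,
    tau: np.ndarray,
    max_iter: int = 500,
) -> tuple[np.ndarray, float, float, int, bool]:
    # initialize at the coarse direction scaled to match total signal
    pred_dir = r * (mu @ tau)
    denom = float(w @ pred_dir**2)
    scale = float(w @ (pred_dir * y)) / denom if denom > 0 else 1.0
    beta0 = tau * max(scale, 0.0)
    lam_val = _auto_lambda(beta0, y, mu, w, r) if lam == "auto" else float(lam)

    res = minimize(
        loss_and_gradient,
        beta0,
        args=(y, mu, w, r, lam_val),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * mu.shape[1],
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-10},
    )
    beta = np.maximum(res.x, 0.0)
    return beta, lam_val, float(res.fun), int(res.nit), bool(res.success)


def solve_proportions(
    y: np.ndarray,
    panel: ReferencePanel,
    w_c: np.ndarray | None = None,
    lam="auto",
    *,
    correction: str = "adaptive",
    mu_compound: np.ndarray | None = None,
    max_iter: int = 500,
) -> DeconvolutionResult:
    """Full pipeline for a single sample aligned to the panel's genes.

    ``correction='adaptive'`` learns per-gene factors from the coarse
    NNLS pass; ``'none'`` forces r = 1 (no platform correction).
    ``mu_compound`` overrides the vector used for the coarse pass (the
    replicate-group mean); by default the sample itself is used.
    """
    samples = CompoundSampleSet(
        counts=np.asarray(y, dtype=float)[:, None],
        gene_ids=list(panel.selected_genes),
        sample_ids=["sample"],
    )
    return deconvolute(
        samples,
        panel,
        weights=w_c,
        lam=lam,
        correction=correction,
        mu_compound_override=mu_compound,
        max_iter=max_iter,
    )


def deconvolute(
    samples: CompoundSampleSet,
    panel: ReferencePanel,
    weights: CrossSampleWeights | np.ndarray | None = None,
    lam="auto",
    *,
    correction: str = "adaptive",
    mu_compound_override: np.ndarray | None = None,
    max_iter: int = 500,
) -> DeconvolutionResult:
    """Estimate proportions for every sample independently.

    Coarse estimates and correction factors are computed once per
    replicate group from the group's mean expression and shared by its
    members. Output rows satisfy theta >= 0, sum(theta) = 1.
    """
    if correction not in ("adaptive", "none"):
        raise ValidationError(f"unknown correction mode {correction!r}")

    sample_gene_index = {g: i for i, g in enumerate(samples.gene_ids)}
    common = [g for g in panel.selected_genes if g in sample_gene_index]
    overlap = len(common) / panel.n_genes
    logger.info("gene overlap with panel: %d/%d (%.1f%%)", len(common), panel.n_genes, 100 * overlap)
    if overlap < 0.5:
        raise ValidationError(
            f"only {100 * overlap:.1f}% of panel genes found in the sample matrix (< 50%)"
        )
    panel_rows = [panel.selected_genes.index(g) for g in common]
    sample_rows = [sample_gene_index[g] for g in common]
    mu = panel.mu[panel_rows]
    w_s = panel.specificity_weight[panel_rows]

    if weights is None:
        w_c = np.ones(len(common))
    elif isinstance(weights, CrossSampleWeights):
        w_c = weights.aligned_to(common)
    else:
        w_c = np.asarray(weights, dtype=float)
        if w_c.shape != (len(common),):
            raise ValidationError("weight vector must align with the panel/sample gene overlap")
    w = w_c * w_s

    Y = samples.counts[sample_rows]
    S, K = len(samples.sample_ids), panel.n_types

    sub_panel = ReferencePanel(
        selected_genes=common,
        cell_types=panel.cell_types,
        mu=mu,
        var=panel.var[panel_rows],
        dispersion=panel.dispersion[panel_rows],
        success_prob=panel.success_prob[panel_rows],
        specificity_weight=w_s,
        fit_flag=panel.fit_flag[panel_rows],
        gene_mode=panel.gene_mode,
        metadata=panel.metadata,
    )

    groups: dict[str, list[int]] = {}
    for j, sid in enumerate(samples.sample_ids):
        groups.setdefault(samples.group_of(sid), []).append(j)

    theta = np.zeros((S, K))
    beta_raw = np.zeros((S, K))
    tau_all = np.zeros((S, K))
    lam_used = np.zeros(S)
    loss_val = np.zeros(S)
    n_iter = np.zeros(S, dtype=int)
    converged = np.zeros(S, dtype=bool)
    corr_factors: dict[str, np.ndarray] = {}
    corr_mask: dict[str, np.ndarray] = {}

    for gname, members in groups.items():
        mu_c = (
            np.asarray(mu_compound_override, dtype=float)
            if mu_compound_override is not None
            else Y[:, members].mean(axis=1)
        )
        tau = coarse_estimate(mu_c, sub_panel)
        if correction == "adaptive":
            r, valid = compute_correction_factors(mu_c, sub_panel, tau)
        else:
            r, valid = np.ones(len(common)), np.ones(len(common), dtype=bool)
        corr_factors[gname] = r
        corr_mask[gname] = valid
        use = valid & (w > 0)
        for j in members:
            beta, lv, fv, nit, ok = _solve_single(
                Y[use, j], mu[use], w[use], r[use], lam, tau, max_iter=max_iter
            )
            total = beta.sum()
            if total <= 0:
                warnings.warn(
                    f"sample {samples.sample_ids[j]!r}: all coefficients zero; uniform theta",
                    stacklevel=2,
                )
                th, ok = np.full(K, 1.0 / K), False
            else:
                th = beta / total
            theta[j], beta_raw[j], tau_all[j] = th, beta, tau
            lam_used[j], loss_val[j], n_iter[j], converged[j] = lv, fv, nit, ok

    assert np.all(np.abs(theta.sum(axis=1) - 1.0) < _SIMPLEX_TOL)
    return DeconvolutionResult(
        sample_ids=list(samples.sample_ids),
        cell_types=list(panel.cell_types),
        theta=theta,
        beta_raw=beta_raw,
        tau_coarse=tau_all,
        lambda_used=lam_used,
        loss_value=loss_val,
        n_iter=n_iter,
        converged=converged,
        gene_ids=common,
        correction_factors=corr_factors,
        correction_mask=corr_mask,
    )
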