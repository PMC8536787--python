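"""Per-gene negative-binomial fitting.

UMI counts for one gene within one cell type (or across pseudo-samples)
are modelled as NB(lambda, p) where ``lambda`` is the dispersion (size)
parameter and ``p`` the success probability, so that

    mean     mu     = lambda * p / (1 - p)
    variance sigma2 = lambda * p / (1 - p)**2

Underdispersed vectors (sample variance <= sample mean) cannot support an
NB fit on the interior of the parameter space and fall back to Poisson
(sigma2 = mu); all-zero vectors are flagged and carry mu = sigma2 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .errors import ValidationError

FLAG_NB_OK = "nb_ok"
FLAG_POISSON = "poisson_fallback"
FLAG_ALL_ZERO = "all_zero"

_LAMBDA_LO, _LAMBDA_HI = 1e-6, 1e6
_P_LO, _P_HI = 1e-9, 1.0 - 1e-9


@dataclass(frozen=True)
class NBFit:
    """Result of a single negative-binomial fit."""

    lambda_: float
    p: float
    mu: float
    var: float
    flag: str


def nb_neg_loglik(lam: float, p: float, values: np.ndarray, weights: np.ndarray) -> float:
    """Negative log-likelihood of NB(lam, p) on compacted counts.

    ``values`` are the distinct observed counts, ``weights`` their
    multiplicities; compaction makes repeated evaluation cheap.
    """
    n = weights.sum()
    ll = (
        float(weights @ gammaln(values + lam))
        - n * gammaln(lam)
        - float(weights @ gammaln(values + 1.0))
        + n * lam * np.log1p(-p)
        + float(weights @ values) * np.log(p)
    )
    return -ll


def _profile_negloglik(log_lam: float, values: np.ndarray, weights: np.ndarray, xbar: float) -> float:
    # for fixed lambda the MLE of p matches the sample mean: p = xbar/(lam+xbar)
    lam = np.exp(log_lam)
    p = xbar / (lam + xbar)
    p = min(max(p, _P_LO), _P_HI)
    return nb_neg_loglik(lam, p, values, weights)


def _validate_counts(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValidationError("counts vector must be 1-D and non-empty")
    if not np.all(np.isfinite(x)):
        raise ValidationError("counts vector contains non-finite values")
    if np.any(x < 0):
        raise ValidationError("counts must be non-negative")
    rounded = np.rint(x)
    if not np.allclose(x, rounded, atol=1e-8):
        raise ValidationError("counts must be integral UMI counts")
    return rounded


def fit_nb_profile(counts_vector) -> NBFit:
    """Fit NB(lambda, p) to one vector of raw UMI counts by MLE.

    Returns the fitted parameters together with the implied mean and
    variance and a flag describing which branch was taken.
    """
    x = _validate_counts(np.asarray(counts_vector))
    n = x.size
    xbar = float(x.mean())

    if xbar == 0.0:
        return NBFit(0.0, 0.0, 0.0, 0.0, FLAG_ALL_ZERO)

    s2 = float(x.var(ddof=1)) if n >= 2 else 0.0
    if s2 <= xbar:
        return NBFit(0.0, 0.0, xbar, xbar, FLAG_POISSON)

    values, weights = np.unique(x, return_counts=True)
    weights = weights.astype(float)

    # method-of-moments lambda, used only to sanity-check the bounded search
    lam_mom = xbar * xbar / (s2 - xbar)
    lam_mom = min(max(lam_mom, _LAMBDA_LO), _LAMBDA_HI)

    res = minimize_scalar(
        _profile_negloglik,
        bounds=(np.log(_LAMBDA_LO), np.log(_LAMBDA_HI)),
        args=(values, weights, xbar),
        method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(np.exp(res.x)) if res.success else lam_mom
    p = xbar / (lam + xbar)
    p = min(max(p, _P_LO), _P_HI)
    mu = lam * p / (1.0 - p)
    var = lam * p / (1.0 - p) ** 2
    if not np.isfinite(var) or var <= mu:
        # boundary fit collapsed to (quasi-)Poisson
        return NBFit(0.0, 0.0, xbar, xbar, FLAG_POISSON)
    return NBFit(lam, p, mu, var, FLAG_NB_OK)
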