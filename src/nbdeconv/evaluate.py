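"""Evaluation of estimated against true compositions.

Concordance between an estimated proportion vector theta and the truth
theta0 is summarized by the mean absolute difference mAD, the root mean
square deviation RMSD (both the standard rooted form and the unrooted
mean-squared variant are reported), and Pearson / Spearman correlations.
Presence calls (a cell type deemed detected when its estimate exceeds a
threshold) support ROC/AUC analysis and detection-rate curves for rare
types. A leave-one-out harness rebuilds the reference without each
subject, deconvolutes that subject's pseudo-bulk and scores it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .deconvolve import CompoundSampleSet, deconvolute
from .errors import ConfigurationError, ValidationError
from .reference import SingleCellReferenceData, build_reference
from .simulate import synthesize_bulk
from .weights import MODE_BOOTSTRAP, compute_cross_sample_weights

logger = logging.getLogger(__name__)


@dataclass
class ConcordanceMetrics:
    mad: float
    rmsd: float
    msd_literal: float  # unrooted mean-squared variant
    pearson: float
    spearman: float


@dataclass
class EvaluationReport:
    per_sample: pd.DataFrame
    pooled: ConcordanceMetrics
    roc_points: pd.DataFrame | None = None
    auc: float | None = None
    detection_rates: dict = field(default_factory=dict)


def concordance_metrics(theta, theta0) -> ConcordanceMetrics:
    """mAD, RMSD (rooted and literal mean-squared), Pearson and Spearman.

    Correlations need length >= 2; zero-variance inputs make them
    undefined and are reported as NaN with a warning. Spearman uses
    average ranks for ties.
    """
    t = np.asarray(theta, dtype=float)
    t0 = np.asarray(theta0, dtype=float)
    if t.shape != t0.shape:
        raise ValidationError("theta and theta0 must have equal length")
    K = t.size
    diff = t - t0
    mad = float(np.abs(diff).mean())
    msd = float((diff**2).mean())
    rmsd = float(np.sqrt(msd))
    if K < 2 or np.ptp(t) == 0 or np.ptp(t0) == 0:
        warnings.warn("correlation undefined for constant or length-1 input", stacklevel=2)
        rp = rs = float("nan")
    else:
        rp = float(pearsonr(t, t0).statistic)
        rs = float(spearmanr(t, t0).statistic)
    return ConcordanceMetrics(mad=mad, rmsd=rmsd, msd_literal=msd, pearson=rp, spearman=rs)


def roc_auc(estimates, presence_truth) -> tuple[pd.DataFrame, float]:
    """ROC over presence calls, pooling all (sample, type) pairs.

    The detection threshold sweeps every distinct estimate value plus the
    {0, 1} endpoints; a pair is called present when its estimate exceeds
    the threshold. AUC by the trapezoid rule. Tied scores move together
    (one threshold step).
    """
    est = np.asarray(estimates, dtype=float).ravel()
    truth = np.asarray(presence_truth, dtype=bool).ravel()
    if est.shape != truth.shape:
        raise ValidationError("estimates and presence_truth shapes must match")
    n_pos, n_neg = int(truth.sum()), int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("presence truth must contain both positives and negatives")
    thresholds = np.unique(np.concatenate([est, [0.0, 1.0]]))[::-1]
    rows = []
    for t in thresholds:
        call = est > t
        tpr = float(np.sum(call & truth)) / n_pos
        fpr = float(np.sum(call & ~truth)) / n_neg
        rows.append((t, fpr, tpr))
    pts = pd.DataFrame(rows, columns=["threshold", "fpr", "tpr"])
    pts = pd.concat(
        [pts, pd.DataFrame([(float("inf"), 0.0, 0.0), (-float("inf"), 1.0, 1.0)], columns=pts.columns)]
    )
    pts = pts.sort_values(["fpr", "tpr"]).drop_duplicates(["fpr", "tpr"]).reset_index(drop=True)
    auc = float(np.trapezoid(pts["tpr"], pts["fpr"]))
    return pts, auc


def detection_rate(estimates_for_rare_type, threshold: float = 0.005) -> float:
    """Fraction of repetitions whose estimate strictly exceeds the threshold."""
    est = np.asarray(estimates_for_rare_type, dtype=float)
    if est.size < 1:
        raise ValidationError("need at least one repetition")
    return float(np.mean(est > threshold))


def evaluate_samples(theta: np.ndarray, theta0: np.ndarray, sample_ids=None) -> EvaluationReport:
    """Per-sample metrics plus pooled metrics over all (sample, type) entries."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    theta0 = np.atleast_2d(np.asarray(theta0, dtype=float))
    if theta.shape != theta0.shape:
        raise ValidationError("theta and theta0 must have the same shape")
    ids = list(sample_ids) if sample_ids is not None else [f"s{i}" for i in range(theta.shape[0])]
    rows = []
    for i, sid in enumerate(ids):
        m = concordance_metrics(theta[i], theta0[i])
        rows.append((sid, m.mad, m.rmsd, m.msd_literal, m.pearson, m.spearman))
    per_sample = pd.DataFrame(
        rows, columns=["sample_id", "mad", "rmsd", "msd_literal", "pearson", "spearman"]
    ).set_index("sample_id")
    pooled = concordance_metrics(theta.ravel(), theta0.ravel())
    return EvaluationReport(per_sample=per_sample, pooled=pooled)


def leave_one_out_benchmark(
    ref: SingleCellReferenceData,
    lam="auto",
    *,
    gene_mode: str = "markers",
    weight_mode: str = MODE_BOOTSTRAP,
    B: int = 20,
    seed: int = 0,
    top_n: int = 200,
    correction: str = "adaptive",
) -> pd.DataFrame:
    """Leave-one-subject-out benchmark on an annotated reference.

    For each subject, the panel and gene weights are rebuilt from the
    remaining subjects, the held-out subject's pseudo-bulk is
    deconvoluted, and the estimate is scored against the subject's
    cell-count truth. Returns one metrics row per subject (plus theta /
    theta0 columns prefixed ``est_`` / ``true_``).
    """
    if ref.subject_labels is None:
        raise ConfigurationError("leave-one-out requires subject labels")
    subjects = sorted(set(map(str, ref.subject_labels)))
    if len(subjects) < 3:
        raise ConfigurationError(f"leave-one-out requires >= 3 subjects, found {len(subjects)}")

    rows = []
    for held_out in subjects:
        keep = ref.subject_labels != held_out
        train = SingleCellReferenceData(
            counts=ref.counts[:, keep],
            gene_ids=list(ref.gene_ids),
            cell_ids=[c for c, k in zip(ref.cell_ids, keep) if k],
            cell_type_labels=ref.cell_type_labels[keep],
            subject_labels=ref.subject_labels[keep],
            min_cells_per_type=min(ref.min_cells_per_type, 3),
        )
        panel = build_reference(train, gene_mode=gene_mode, seed=seed, top_n=top_n)
        n_train_subj = len(set(map(str, train.subject_labels)))
        mode = "reference_replicates" if n_train_subj >= 3 else MODE_BOOTSTRAP
        weights = compute_cross_sample_weights(train, mode, B=B, seed=seed)

        y, truth = synthesize_bulk(ref, held_out)
        samples = CompoundSampleSet(
            counts=y[:, None], gene_ids=list(ref.gene_ids), sample_ids=[held_out]
        )
        res = deconvolute(samples, panel, weights=weights, lam=lam, correction=correction)

        # align truth (over ref.cell_types) to the panel's types
        t0 = np.array(
            [truth.theta0[truth.cell_types.index(ct)] if ct in truth.cell_types else 0.0
             for ct in res.cell_types]
        )
        m = concordance_metrics(res.theta[0], t0)
        row = {
            "subject": held_out,
            "mad": m.mad,
            "rmsd": m.rmsd,
            "pearson": m.pearson,
            "spearman": m.spearman,
        }
        row.update({f"est_{ct}": v for ct, v in zip(res.cell_types, res.theta[0])})
        row.update({f"true_{ct}": v for ct, v in zip(res.cell_types, t0)})
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject")
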