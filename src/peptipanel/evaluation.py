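"""Validation-phase statistics.

Sensitivity and specificity with exact binomial (Clopper–Pearson) 95%
confidence intervals, ROC curves with the Mann–Whitney concordance AUC
(ties count 0.5) and a DeLong variance CI, and multi-cohort pooling by
summing confusion counts.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .types import ConfusionCounts, EvalReport, ScoreResult

logger = logging.getLogger("peptipanel")


def clopper_pearson(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial two-sided CI for x successes out of n."""
    if not (0 <= x <= n) or n <= 0:
        raise ValidationError(f"invalid counts x={x}, n={n}")
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def confusion_from_predictions(
    predictions: Sequence[str],
    truth: Sequence[str],
    case_label: str = "case",
    cohort_label: str = "",
) -> ConfusionCounts:
    if len(predictions) != len(truth):
        raise ValidationError(
            f"length mismatch: {len(predictions)} predictions vs {len(truth)} truths"
        )
    tp = fp = tn = fn = 0
    for p, t in zip(predictions, truth):
        if t == case_label:
            tp += p == case_label
            fn += p != case_label
        else:
            fp += p == case_label
            tn += p != case_label
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, cohort_label=cohort_label)


def confusion_metrics(counts: ConfusionCounts) -> EvalReport:
    """Sensitivity/specificity with exact binomial 95% CIs.

    A metric whose denominator is zero (a cohort with no positives, or no
    negatives) is reported as undefined (None), never as 0.
    """
    if counts.positives == 0 and counts.negatives == 0:
        raise ValidationError("cohort has neither positives nor negatives")
    sens = sens_ci = spec = spec_ci = None
    if counts.positives > 0:
        sens = counts.tp / counts.positives
        sens_ci = clopper_pearson(counts.tp, counts.positives)
    if counts.negatives > 0:
        spec = counts.tn / counts.negatives
        spec_ci = clopper_pearson(counts.tn, counts.negatives)
    return EvalReport(
        counts=counts,
        sensitivity=sens,
        sensitivity_ci=sens_ci,
        specificity=spec,
        specificity_ci=spec_ci,
    )


def _auc_concordance(case_scores: np.ndarray, control_scores: np.ndarray) -> float:
    """AUC = P(case score > control score) + 0.5 P(tie), via midranks."""
    n, m = case_scores.size, control_scores.size
    pooled = np.concatenate([case_scores, control_scores])
    ranks = stats.rankdata(pooled)
    u = ranks[:n].sum() - n * (n + 1) / 2.0
    return float(u / (n * m))


def _delong_variance(case_scores: np.ndarray, control_scores: np.ndarray, auc: float) -> float:
    """DeLong's structural-components variance of the AUC estimate."""
    n, m = case_scores.size, control_scores.size
    # V10[i] = P(control < case_i) + 0.5 P(tie); V01[j] symmetric
    v10 = np.array(
        [((control_scores < c).sum() + 0.5 * (control_scores == c).sum()) / m for c in case_scores]
    )
    v01 = np.array(
        [((case_scores > c).sum() + 0.5 * (case_scores == c).sum()) / n for c in control_scores]
    )
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    return s10 / n + s01 / m


def roc_auc(
    scores: Sequence[float],
    truth: Sequence[str],
    case_label: str = "case",
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float], list[tuple[float, float, float]]]:
    """AUC with DeLong 95% CI and the ROC curve.

    Returns (auc, (lo, hi), points) where each point is
    (threshold, false-positive rate, true-positive rate) under the
    "predicted positive at score >= threshold" convention, plus the
    (inf, 0, 0) anchor.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray([str(t) for t in truth])
    if scores.size != truth.size:
        raise ValidationError("scores and truth must align")
    is_case = truth == case_label
    if is_case.all() or (~is_case).all():
        raise ValidationError("both classes must be present")
    case_scores = scores[is_case]
    control_scores = scores[~is_case]

    auc = _auc_concordance(case_scores, control_scores)
    var = _delong_variance(case_scores, control_scores, auc)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    points = [(float("inf"), 0.0, 0.0)]
    for thr in np.unique(scores)[::-1]:
        pred = scores >= thr
        tpr = (pred & is_case).sum() / is_case.sum()
        fpr = (pred & ~is_case).sum() / (~is_case).sum()
        points.append((float(thr), float(fpr), float(tpr)))
    return auc, ci, points


def evaluate_scores(
    results: Sequence[ScoreResult],
    truth: Sequence[str],
    case_label: str = "case",
    cohort_label: str = "",
) -> EvalReport:
    """Full per-cohort report from scored samples and true labels."""
    counts = confusion_from_predictions(
        [r.predicted for r in results], list(truth), case_label, cohort_label
    )
    report = confusion_metrics(counts)
    truth_arr = [str(t) for t in truth]
    has_case = any(t == case_label for t in truth_arr)
    has_control = any(t != case_label for t in truth_arr)
    if has_case and has_control:
        auc, ci, _ = roc_auc([r.score for r in results], truth_arr, case_label)
        report.auc, report.auc_ci = auc, ci
    return report


def pooled_metrics(reports: Sequence[ConfusionCounts]) -> EvalReport:
    """Sum confusion counts across cohorts, then compute metrics on the pool."""
    if not reports:
        raise ValidationError("no cohorts to pool")
    total = reports[0]
    for c in reports[1:]:
        total = total + c
    return confusion_metrics(total)
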