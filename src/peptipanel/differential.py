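"""Differential peptide discovery.

The panel-discovery recipe: keep peptides detected in at least 70% of the
samples of at least one group, compare groups per peptide with a two-sided
Wilcoxon rank-sum test (zeros enter as true zero amplitudes, mid-ranks for
ties), adjust over exactly the filtered set with Benjamini–Hochberg, and
keep adjusted p < alpha.  Each surviving peptide carries a signed
fold-change: +r when cases are r-fold higher, -r when r-fold lower, so
|FC| >= 1 always.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PowerError, ValidationError
from .types import AmplitudeMatrix

logger = logging.getLogger("peptipanel")


@dataclass
class DifferentialConfig:
    freq_threshold: float = 0.70
    alpha: float = 0.05
    wilcoxon_mode: str = "auto"  # exact | approximate | auto

    def __post_init__(self) -> None:
        if not (0 < self.freq_threshold <= 1):
            raise ValidationError("freq_threshold must be in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")


@dataclass
class PanelEntry:
    peptide_id: str
    p_raw: float
    p_adj: float
    fold_change: float  # signed, |FC| >= 1; +inf / nan sentinels for zero means
    direction: str  # "up" or "down" in cases
    freq_case: float
    freq_control: float


def frequency_filter(
    matrix: AmplitudeMatrix,
    labels: pd.Series,
    threshold: float = 0.70,
    case_label: Optional[str] = None,
    control_label: Optional[str] = None,
) -> list[str]:
    """Peptides detected in >= threshold of samples in at least one group.

    The boundary is inclusive: detection in exactly 70% of a group keeps the
    peptide.
    """
    case_label, control_label = _resolve_labels(labels, case_label, control_label)
    detected = matrix.amplitudes > 0
    freq_a = detected.loc[labels == case_label].mean(axis=0)
    freq_b = detected.loc[labels == control_label].mean(axis=0)
    keep = (freq_a >= threshold) | (freq_b >= threshold)
    kept = list(matrix.amplitudes.columns[keep])
    logger.info(
        "frequency_filter: %d of %d peptides pass the %.0f%% rule",
        len(kept), matrix.n_peptides, 100 * threshold,
    )
    return kept


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Returns (U statistic of ``x``, two-sided p).  ``auto`` uses exact
    enumeration when min(n, m) <= 8 and the pooled data has no ties, else a
    normal approximation with tie-corrected variance and 0.5 continuity
    correction.  p is clipped to (0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    if mode == "auto":
        method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    elif mode == "exact":
        method = "exact"
    elif mode == "approximate":
        method = "asymptotic"
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    if method == "exact" and has_ties:
        # exact null distribution assumes distinct values; fall back to the
        # permutation definition only for the all-tied degenerate case
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                                 use_continuity=True)
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                                 use_continuity=True)
    p = min(float(res.pvalue), 1.0)
    if p <= 0.0:
        p = np.nextafter(0.0, 1.0)
    return float(res.statistic), p


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adj(i) = min over j >= i (in the sorted order) of p(j) * m / j, capped
    at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def fold_change(case_amps: Sequence[float], control_amps: Sequence[float]) -> float:
    """Signed mean fold-change with zeros included in the means.

    r = mean(case)/mean(control); returns +r if r >= 1 else -1/r.  A zero
    control mean with a positive case mean gives +inf; both zero gives NaN.
    """
    case_amps = np.asarray(case_amps, dtype=float)
    control_amps = np.asarray(control_amps, dtype=float)
    if case_amps.size == 0 or control_amps.size == 0:
        raise ValidationError("groups must be non-empty")
    mc, mn = case_amps.mean(), control_amps.mean()
    if mn == 0:
        return math.inf if mc > 0 else math.nan
    r = mc / mn
    return r if r >= 1 else -1.0 / r


def _resolve_labels(labels, case_label, control_label):
    uniq = pd.unique(labels)
    if case_label is None or control_label is None:
        if len(uniq) != 2:
            raise ValidationError(
                f"expected exactly two groups, got {sorted(map(str, uniq))}; "
                "pass case_label/control_label explicitly"
            )
        # deterministic: 'case' if present, else lexicographically last as case
        if case_label is None:
            case_label = "case" if "case" in uniq else sorted(map(str, uniq))[-1]
        if control_label is None:
            control_label = next(str(u) for u in sorted(map(str, uniq)) if str(u) != case_label)
    for lbl in (case_label, control_label):
        if lbl not in set(map(str, uniq)):
            raise ValidationError(f"unknown group label {lbl!r}")
    return case_label, control_label


def discover_panel(
    matrix: AmplitudeMatrix,
    labels: Optional[pd.Series] = None,
    config: Optional[DifferentialConfig] = None,
    case_label: Optional[str] = None,
    control_label: Optional[str] = None,
) -> list[PanelEntry]:
    """Run the full discovery funnel and return the significant panel.

    frequency filter -> per-peptide Wilcoxon -> BH over the filtered set ->
    keep p_adj < alpha, sorted by (p_adj, peptide_id).
    """
    config = config or DifferentialConfig()
    if labels is None:
        labels = matrix.groups
    if labels is None:
        raise ValidationError("no group labels on matrix and none supplied")
    labels = labels.reindex(matrix.amplitudes.index).astype(str)
    case_label, control_label = _resolve_labels(labels, case_label, control_label)
    n_case = int((labels == case_label).sum())
    n_control = int((labels == control_label).sum())
    if min(n_case, n_control) < 3:
        raise PowerError(
            f"group sizes {n_case} vs {n_control}: fewer than 3 samples in a group "
            "gives the rank test essentially no power"
        )

    kept = frequency_filter(matrix, labels, config.freq_threshold, case_label, control_label)
    if not kept:
        return []
    case_rows = matrix.amplitudes.loc[labels == case_label, kept]
    control_rows = matrix.amplitudes.loc[labels == control_label, kept]

    p_raw = np.array(
        [
            wilcoxon_rank_sum(case_rows[pid].values, control_rows[pid].values,
                              mode=config.wilcoxon_mode)[1]
            for pid in kept
        ]
    )
    p_adj = bh_adjust(p_raw)

    entries = []
    for pid, pr, pa in zip(kept, p_raw, p_adj):
        if pa >= config.alpha:
            continue
        fc = fold_change(case_rows[pid].values, control_rows[pid].values)
        entries.append(
            PanelEntry(
                peptide_id=pid,
                p_raw=float(pr),
                p_adj=float(pa),
                fold_change=fc,
                direction="up" if fc > 0 else "down",
                freq_case=float((case_rows[pid] > 0).mean()),
                freq_control=float((control_rows[pid] > 0).mean()),
            )
        )
    entries.sort(key=lambda e: (e.p_adj, e.peptide_id))
    logger.info(
        "discover_panel: %d peptides tested, %d significant at adjusted p < %g",
        len(kept), len(entries), config.alpha,
    )
    return entries


def panel_to_frame(entries: Sequence[PanelEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peptide_id": [e.peptide_id for e in entries],
            "p_raw": [e.p_raw for e in entries],
            "p_adj": [e.p_adj for e in entries],
            "fold_change": [e.fold_change for e in entries],
            "direction": [e.direction for e in entries],
            "freq_case": [e.freq_case for e in entries],
            "freq_control": [e.freq_control for e in entries],
        }
    )
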