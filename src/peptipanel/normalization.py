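"""Housekeeping-peptide normalization.

Urine concentration varies several-fold between voids, so raw amplitudes of
two samples are not comparable.  A set of housekeeping peptides — present in
nearly every sample and varying little — serves as an internal standard: each
sample is rescaled by the median ratio of the reference amplitude to the
observed amplitude over its detected housekeeping peptides (a median-of-ratios
estimator, robust to a differential peptide accidentally entering the set).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NormalizationError, SelectionError, ValidationError
from .types import AmplitudeMatrix

logger = logging.getLogger("peptipanel")


@dataclass
class NormalizationReference:
    """Housekeeping peptide ids and their reference (cohort median) amplitudes."""

    peptide_ids: list[str]
    reference_amplitudes: list[float]

    def __post_init__(self) -> None:
        if len(self.peptide_ids) != len(self.reference_amplitudes):
            raise ValidationError("peptide_ids and reference_amplitudes must align")
        if len(set(self.peptide_ids)) != len(self.peptide_ids):
            raise ValidationError("housekeeping peptide ids must be unique")
        if any(a <= 0 for a in self.reference_amplitudes):
            raise ValidationError("reference amplitudes must be > 0")

    def as_series(self) -> pd.Series:
        return pd.Series(self.reference_amplitudes, index=self.peptide_ids, dtype=float)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"peptide_id": self.peptide_ids, "reference_amplitude": self.reference_amplitudes}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "NormalizationReference":
        df = pd.read_csv(path, sep="\t", dtype={"peptide_id": str})
        return cls(df["peptide_id"].tolist(), df["reference_amplitude"].astype(float).tolist())


def select_housekeeping(
    matrix: AmplitudeMatrix, n_select: int = 29, min_freq: float = 0.90
) -> NormalizationReference:
    """Pick the n_select most stable high-frequency peptides as the reference.

    Candidates must be detected in at least ``min_freq`` of the samples; among
    them the ``n_select`` with lowest coefficient of variation of
    log-amplitude over detected samples win (ties broken by peptide id).  The
    reference amplitude of each is its median over detected samples.
    """
    freq = matrix.detection_frequency()
    candidates = freq.index[freq >= min_freq]
    if len(candidates) < n_select:
        raise SelectionError(
            f"only {len(candidates)} peptides detected in >= {min_freq:.0%} of samples; "
            f"{n_select} required"
        )
    amp = matrix.amplitudes[candidates]
    log_amp = np.log(amp.where(amp > 0))
    cv = log_amp.std(axis=0, ddof=1) / log_amp.mean(axis=0).abs()
    ranked = sorted(candidates, key=lambda pid: (cv[pid], pid))
    chosen = ranked[:n_select]
    reference = [float(amp[pid][amp[pid] > 0].median()) for pid in chosen]
    logger.info(
        "select_housekeeping: %d candidates at freq >= %.2f, %d selected",
        len(candidates), min_freq, n_select,
    )
    return NormalizationReference(list(chosen), reference)


def normalize_row(
    row: pd.Series, reference: NormalizationReference, min_detected: int = 15
) -> tuple[pd.Series, float]:
    """Rescale one sample's amplitudes against the housekeeping reference.

    factor = median over detected housekeeping peptides of
    (reference_amplitude / observed_amplitude); zeros stay zero.
    """
    ref = reference.as_series()
    present = ref.index.intersection(row.index)
    obs = row[present]
    detected = obs[obs > 0]
    if len(detected) < min_detected:
        raise NormalizationError(
            f"sample {row.name!r}: only {len(detected)} of {len(ref)} housekeeping "
            f"peptides detected (minimum {min_detected})"
        )
    factor = float((ref[detected.index] / detected).median())
    return row * factor, factor


def normalize_matrix(
    matrix: AmplitudeMatrix, reference: NormalizationReference, min_detected: int = 15
) -> tuple[AmplitudeMatrix, pd.Series]:
    """Normalize every sample; returns the scaled matrix and per-sample factors."""
    rows = {}
    factors = {}
    for sid in matrix.sample_ids:
        scaled, f = normalize_row(matrix.amplitudes.loc[sid], reference, min_detected)
        rows[sid] = scaled
        factors[sid] = f
    out = pd.DataFrame(rows).T.reindex(matrix.amplitudes.index)
    out.columns = matrix.amplitudes.columns
    logger.info(
        "normalize_matrix: %d samples scaled; factor range [%.3g, %.3g]",
        matrix.n_samples, min(factors.values()), max(factors.values()),
    )
    return AmplitudeMatrix(out, matrix.groups), pd.Series(factors, name="scale_factor")
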