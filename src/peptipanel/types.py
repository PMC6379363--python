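"""Domain types shared across pipeline stages.

The coordinate system of CE-MS urinary peptidomics is (neutral mass in
Daltons, CE migration time in minutes); a peptide in one sample additionally
carries a normalized signal amplitude.  Amplitude 0 always encodes
"not detected" — the amplitude matrix is dense with a zero sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Mass of a proton in Daltons, used for every m/z <-> neutral-mass conversion.
PROTON_MASS = 1.00728

#: Default instrument acquisition window in m/z (Thomson).
DEFAULT_MZ_WINDOW = (350.0, 3000.0)


@dataclass(frozen=True)
class IonPeak:
    """One charged MS signal as it comes off the instrument.

    ``charge`` may be ``None`` when the charge state could not be read from
    the isotope pattern; deconvolution then hypothesizes charges.
    """

    mz: float
    charge: Optional[int]
    intensity: float
    migration_time: float

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValidationError(f"intensity must be >= 0, got {self.intensity}")
        if self.charge is not None and self.charge < 1:
            raise ValidationError(f"charge must be >= 1 when present, got {self.charge}")
        if self.migration_time < 0:
            raise ValidationError("migration_time must be >= 0")

    def neutral_mass(self, charge: Optional[int] = None) -> float:
        """Neutral mass M = z * (m/z - proton) under the given charge."""
        z = charge if charge is not None else self.charge
        if z is None:
            raise ValidationError("charge unknown; pass an explicit hypothesis")
        return z * (self.mz - PROTON_MASS)


@dataclass(frozen=True)
class NeutralPeptideSignal:
    """A deconvoluted peptide observation: neutral mass, MT, amplitude."""

    mass: float
    migration_time: float
    amplitude: float
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValidationError(f"mass must be > 0, got {self.mass}")
        if self.amplitude < 0:
            raise ValidationError(f"amplitude must be >= 0, got {self.amplitude}")


@dataclass
class SampleProfile:
    """All peptide signals of one urine sample plus cohort metadata."""

    sample_id: str
    group: str
    signals: list[NeutralPeptideSignal] = field(default_factory=list)
    age: Optional[float] = None
    sex: Optional[str] = None
    egfr: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        coords = [(s.mass, s.migration_time) for s in self.signals]
        if len(coords) != len(set(coords)):
            raise ValidationError(
                f"sample {self.sample_id}: duplicate (mass, migration_time) signals"
            )

    @property
    def total_amplitude(self) -> float:
        return float(sum(s.amplitude for s in self.signals))


@dataclass(frozen=True)
class SequencedPeptide:
    """An MS/MS-sequenced peptide available for annotating consensus peptides."""

    sequence: str
    neutral_mass: float
    protein_symbol: str

    def __post_init__(self) -> None:
        if not self.sequence or not self.sequence.isalpha() or not self.sequence.isupper():
            raise ValidationError(f"sequence must match [A-Z]+, got {self.sequence!r}")
        if self.neutral_mass <= 0:
            raise ValidationError("neutral_mass must be > 0")


@dataclass(frozen=True)
class Annotation:
    sequence: str
    protein_symbol: str
    mass_deviation_ppm: float


@dataclass
class ConsensusPeptide:
    """A cross-sample cluster of matched signals; one column of the matrix."""

    peptide_id: str
    reference_mass: float
    reference_mt: float
    annotation: Optional[Annotation] = None


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated peptide."""

    peptide_id: str
    is_marker: bool
    true_effect_fold: float  # signed; positive = up in cases; ±1 for non-markers
    is_housekeeping: bool
    true_mass: float
    true_mt: float


@dataclass(frozen=True)
class ScoreResult:
    """Classifier output for one sample; predicted case iff score >= cutoff."""

    sample_id: str
    score: float
    predicted: str


class AmplitudeMatrix:
    """Dense samples x peptides amplitude table with 0 = not detected.

    Thin wrapper around a pandas DataFrame (rows = samples, columns =
    consensus peptide ids) carrying group labels aligned to the rows.
    """

    def __init__(self, amplitudes: pd.DataFrame, groups: Optional[pd.Series] = None):
        if amplitudes.index.has_duplicates:
            raise ValidationError("duplicate sample_ids in matrix")
        if amplitudes.columns.has_duplicates:
            raise ValidationError("duplicate peptide_ids in matrix")
        if (amplitudes.values < 0).any():
            raise ValidationError("amplitudes must be >= 0")
        self.amplitudes = amplitudes.astype(float)
        if groups is not None:
            groups = groups.reindex(amplitudes.index)
            if groups.isna().any():
                missing = list(groups.index[groups.isna()])
                raise ValidationError(f"samples without group label: {missing}")
        self.groups = groups

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.amplitudes.index)

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.amplitudes.columns)

    @property
    def n_samples(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_peptides(self) -> int:
        return self.amplitudes.shape[1]

    def detection_frequency(self) -> pd.Series:
        """Fraction of samples with amplitude > 0, per peptide."""
        return (self.amplitudes > 0).mean(axis=0)

    def restrict(self, peptide_ids: Sequence[str]) -> "AmplitudeMatrix":
        missing = [p for p in peptide_ids if p not in self.amplitudes.columns]
        if missing:
            raise ValidationError(f"peptides absent from matrix: {missing}")
        return AmplitudeMatrix(self.amplitudes[list(peptide_ids)].copy(), self.groups)

    def with_groups(self, groups: pd.Series) -> "AmplitudeMatrix":
        return AmplitudeMatrix(self.amplitudes.copy(), groups)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AmplitudeMatrix):
            return NotImplemented
        return self.amplitudes.equals(other.amplitudes)

    def __repr__(self) -> str:
        return f"AmplitudeMatrix({self.n_samples} samples x {self.n_peptides} peptides)"


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-cohort confusion table; positives are the case class."""

    tp: int
    fp: int
    tn: int
    fn: int
    cohort_label: str = ""

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be >= 0")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
            cohort_label="pooled",
        )


@dataclass
class EvalReport:
    """Sensitivity/specificity with exact binomial 95% CIs, optional AUC."""

    counts: ConfusionCounts
    sensitivity: Optional[float]
    sensitivity_ci: Optional[tuple[float, float]]
    specificity: Optional[float]
    specificity_ci: Optional[tuple[float, float]]
    auc: Optional[float] = None
    auc_ci: Optional[tuple[float, float]] = None

    def summary(self) -> str:
        def pct(x):
            return "undefined" if x is None else f"{100 * x:.2f}%"

        def ci(c):
            return "" if c is None else f" [{100 * c[0]:.2f}%, {100 * c[1]:.2f}%]"

        lines = [
            f"Cohort: {self.counts.cohort_label or '(unnamed)'}",
            f"  TP={self.counts.tp} FP={self.counts.fp} "
            f"TN={self.counts.tn} FN={self.counts.fn}",
            f"  sensitivity: {pct(self.sensitivity)}{ci(self.sensitivity_ci)}",
            f"  specificity: {pct(self.specificity)}{ci(self.specificity_ci)}",
        ]
        if self.auc is not None:
            lines.append(f"  AUC: {self.auc:.3f}{ci(self.auc_ci) if self.auc_ci else ''}")
        return "\n".join(lines)


def profiles_to_groups(profiles: Sequence[SampleProfile]) -> pd.Series:
    return pd.Series(
        {p.sample_id: p.group for p in profiles},
        name="group",
    ).reindex([p.sample_id for p in profiles])
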