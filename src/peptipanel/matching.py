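"""Cross-sample peptide matching and sequence annotation.

A urinary peptide is identified by its (neutral mass, CE migration time)
coordinate.  Signals from different samples that agree within a ppm mass
tolerance and a migration-time tolerance are the same peptide; clustering
them yields the consensus catalogue and the samples x peptides amplitude
matrix.  Consensus peptides are annotated with MS/MS-derived sequences by
mass (±5 ppm gate) and by predicted migration time, a log-linear model in
mass and effective charge (1 + K + R + 0.5*H — the basic residues carry the
charge at the acidic separation pH).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

from .errors import ConfigError, ValidationError
from .types import (
    AmplitudeMatrix,
    Annotation,
    ConsensusPeptide,
    SampleProfile,
    SequencedPeptide,
    profiles_to_groups,
)

logger = logging.getLogger("peptipanel")


@dataclass
class _Cluster:
    sum_int: float = 0.0
    sum_int_mass: float = 0.0
    sum_int_mt: float = 0.0
    cells: dict[str, float] = field(default_factory=dict)  # sample_id -> summed amplitude

    def add(self, sample_id: str, mass: float, mt: float, amplitude: float) -> None:
        self.sum_int += amplitude
        self.sum_int_mass += amplitude * mass
        self.sum_int_mt += amplitude * mt
        self.cells[sample_id] = self.cells.get(sample_id, 0.0) + amplitude

    @property
    def mean_mass(self) -> float:
        return self.sum_int_mass / self.sum_int

    @property
    def mean_mt(self) -> float:
        return self.sum_int_mt / self.sum_int


def cluster_peptides(
    profiles: Sequence[SampleProfile],
    mass_tol_ppm: float = 50.0,
    mt_tol_min: float = 0.5,
) -> tuple[list[ConsensusPeptide], AmplitudeMatrix]:
    """Cluster per-sample signals into consensus peptides and build the matrix.

    Single-linkage with a cap: signals are sorted by mass; a signal joins the
    most recent cluster whose running intensity-weighted mean mass is within
    ``mass_tol_ppm`` and mean MT within ``mt_tol_min``, else opens a new
    cluster.  Multiple signals of one sample falling into one cluster are
    summed, conserving total amplitude.
    """
    if mass_tol_ppm <= 0 or mt_tol_min <= 0:
        raise ConfigError("tolerances must be > 0")
    records = []
    for p in profiles:
        for s in p.signals:
            records.append((s.mass, s.migration_time, s.amplitude, p.sample_id))
    records.sort(key=lambda r: (r[0], r[3], r[1]))

    clusters: list[_Cluster] = []
    for m, mt, amp, sid in records:
        placed = False
        for c in reversed(clusters):
            mm = c.mean_mass
            if m - mm > 3 * mass_tol_ppm * 1e-6 * mm:
                break
            if abs(m - mm) <= mass_tol_ppm * 1e-6 * mm and abs(mt - c.mean_mt) <= mt_tol_min:
                c.add(sid, m, mt, amp)
                placed = True
                break
        if not placed:
            c = _Cluster()
            c.add(sid, m, mt, amp)
            clusters.append(c)

    clusters.sort(key=lambda c: (c.mean_mass, c.mean_mt))
    width = max(4, len(str(len(clusters))))
    consensus = [
        ConsensusPeptide(
            peptide_id=f"P{i + 1:0{width}d}",
            reference_mass=c.mean_mass,
            reference_mt=c.mean_mt,
        )
        for i, c in enumerate(clusters)
    ]
    sample_ids = [p.sample_id for p in profiles]
    data = np.zeros((len(sample_ids), len(clusters)))
    sidx = {sid: i for i, sid in enumerate(sample_ids)}
    for j, c in enumerate(clusters):
        for sid, amp in c.cells.items():
            data[sidx[sid], j] = amp
    matrix = AmplitudeMatrix(
        pd.DataFrame(data, index=sample_ids, columns=[c.peptide_id for c in consensus]),
        groups=profiles_to_groups(profiles),
    )
    logger.info(
        "cluster_peptides: %d signals from %d samples -> %d consensus peptides",
        len(records), len(profiles), len(consensus),
    )
    return consensus, matrix


def map_to_catalogue(
    profiles: Sequence[SampleProfile],
    consensus: Sequence[ConsensusPeptide],
    mass_tol_ppm: float = 50.0,
    mt_tol_min: float = 0.5,
) -> AmplitudeMatrix:
    """Project new samples onto an existing consensus catalogue.

    Each signal is assigned to the nearest (in ppm) consensus peptide within
    both tolerances; unmatched signals are dropped with a logged count.  Used
    to score validation cohorts against the discovery catalogue.
    """
    ref_mass = np.array([c.reference_mass for c in consensus])
    ref_mt = np.array([c.reference_mt for c in consensus])
    order = np.argsort(ref_mass)
    ref_mass_sorted = ref_mass[order]

    sample_ids = [p.sample_id for p in profiles]
    data = np.zeros((len(profiles), len(consensus)))
    unmatched = 0
    for i, p in enumerate(profiles):
        for s in p.signals:
            tol = mass_tol_ppm * 1e-6 * s.mass
            lo = np.searchsorted(ref_mass_sorted, s.mass - tol)
            hi = np.searchsorted(ref_mass_sorted, s.mass + tol, side="right")
            best = None
            for k in order[lo:hi]:
                if abs(s.migration_time - ref_mt[k]) > mt_tol_min:
                    continue
                dev = abs(s.mass - ref_mass[k]) / ref_mass[k]
                if best is None or dev < best[0]:
                    best = (dev, k)
            if best is None:
                unmatched += 1
            else:
                data[i, best[1]] += s.amplitude
    if unmatched:
        logger.info("map_to_catalogue: %d signal(s) matched no consensus peptide", unmatched)
    return AmplitudeMatrix(
        pd.DataFrame(data, index=sample_ids, columns=[c.peptide_id for c in consensus]),
        groups=profiles_to_groups(profiles),
    )


# -- migration-time model -------------------------------------------------

def effective_charge(sequence: str) -> float:
    """Effective charge at separation pH: 1 + K + R + 0.5*H."""
    if not sequence:
        raise ValidationError("empty sequence")
    return 1.0 + sequence.count("K") + sequence.count("R") + 0.5 * sequence.count("H")


def sequence_mass(sequence: str) -> float:
    """Monoisotopic neutral mass of a peptide sequence."""
    return float(_pmass.fast_mass(sequence))


def predict_migration_time(sequence: str, coefficients: tuple[float, float, float]) -> float:
    """MT = a + b*ln(mass) - c*ln(z_eff): larger peptides migrate later,
    more basic (higher effective charge) peptides earlier."""
    if not sequence:
        raise ValidationError("empty sequence")
    a, b, c = coefficients
    return a + b * math.log(sequence_mass(sequence)) - c * math.log(effective_charge(sequence))


def fit_migration_model(
    calibration: Sequence[tuple[str, float]],
) -> tuple[float, float, float]:
    """Least-squares fit of (a, b, c) from (sequence, observed MT) pairs.

    All three coefficients must come out positive; a calibration set that
    fits with the wrong sign indicates unusable calibrants.
    """
    if len(calibration) < 3:
        raise ValidationError("need at least 3 calibration pairs")
    X = np.array(
        [[1.0, math.log(sequence_mass(s)), -math.log(effective_charge(s))] for s, _ in calibration]
    )
    y = np.array([mt for _, mt in calibration])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b, c = (float(v) for v in coef)
    if a <= 0 or b <= 0 or c <= 0:
        raise ValidationError(f"fitted coefficients not all positive: a={a:.3g} b={b:.3g} c={c:.3g}")
    return a, b, c


def assign_sequence(
    consensus: ConsensusPeptide,
    candidates: Sequence[SequencedPeptide],
    coefficients: tuple[float, float, float],
    max_ppm: float = 5.0,
    mt_window_min: float = 2.0,
) -> ConsensusPeptide:
    """Annotate a consensus peptide with the best-matching sequenced peptide.

    A candidate survives iff its neutral mass deviates by at most ``max_ppm``
    AND its predicted migration time falls within ``mt_window_min`` of the
    consensus MT.  Smallest ppm deviation wins; ties go to the smallest
    predicted-MT deviation, then lexicographic sequence.  With no survivor
    the annotation stays empty.
    """
    survivors = []
    for cand in candidates:
        ppm = abs(cand.neutral_mass - consensus.reference_mass) / consensus.reference_mass * 1e6
        if ppm > max_ppm:
            continue
        mt_dev = abs(predict_migration_time(cand.sequence, coefficients) - consensus.reference_mt)
        if mt_dev > mt_window_min:
            continue
        survivors.append((ppm, mt_dev, cand.sequence, cand))
    out = ConsensusPeptide(
        peptide_id=consensus.peptide_id,
        reference_mass=consensus.reference_mass,
        reference_mt=consensus.reference_mt,
        annotation=consensus.annotation,
    )
    if survivors:
        ppm, _, _, best = min(survivors)
        # keep the signed deviation for the report
        signed = (best.neutral_mass - consensus.reference_mass) / consensus.reference_mass * 1e6
        out.annotation = Annotation(best.sequence, best.protein_symbol, signed)
    return out


def catalogue_to_frame(consensus: Sequence[ConsensusPeptide]) -> pd.DataFrame:
    """Consensus catalogue as a DataFrame for TSV export."""
    return pd.DataFrame(
        {
            "peptide_id": [c.peptide_id for c in consensus],
            "reference_mass": [c.reference_mass for c in consensus],
            "reference_mt": [c.reference_mt for c in consensus],
            "sequence": [c.annotation.sequence if c.annotation else "" for c in consensus],
            "protein_symbol": [c.annotation.protein_symbol if c.annotation else "" for c in consensus],
            "ppm_deviation": [c.annotation.mass_deviation_ppm if c.annotation else np.nan for c in consensus],
        }
    )
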