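"""Delimited-text readers and writers.

TSV is the canonical exchange format for every artifact in the pipeline:
ion-peak lists, per-sample peptide profiles, cohort metadata, amplitude
matrices, panels and references.  All floats are written at full repr
precision so that write -> read round-trips bit-exactly; decimal points
only, never locale-dependent commas.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import FormatError, MissingDataError, ParseError, ValidationError
from .types import (
    DEFAULT_MZ_WINDOW,
    AmplitudeMatrix,
    IonPeak,
    NeutralPeptideSignal,
    SampleProfile,
    SequencedPeptide,
)

logger = logging.getLogger("peptipanel")

PEAKLIST_COLUMNS = ("mz", "charge", "intensity", "migration_time")
PROFILE_COLUMNS = ("mass_da", "migration_time_min", "amplitude")


def _parse_float(value: str, path, line_no: int, column: str) -> float:
    try:
        x = float(value)
    except (TypeError, ValueError):
        raise ParseError(
            f"{path}: line {line_no}: non-numeric value {value!r} in column {column!r}"
        ) from None
    if math.isnan(x):
        raise ParseError(f"{path}: line {line_no}: NaN in column {column!r}")
    return x


def read_peaklist(
    path,
    dialect: Optional[dict[str, str]] = None,
    mz_window: tuple[float, float] = DEFAULT_MZ_WINDOW,
) -> list[IonPeak]:
    """Read an ion-peak TSV into IonPeaks, dropping peaks outside the m/z window.

    ``dialect`` optionally maps canonical column names (mz, charge, intensity,
    migration_time) to the header names actually present in the file.
    """
    path = Path(path)
    dialect = dialect or {}
    colmap = {c: dialect.get(c, c) for c in PEAKLIST_COLUMNS}
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [src for src in colmap.values() if src not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    peaks: list[IonPeak] = []
    dropped = 0
    lo, hi = mz_window
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        rec = dict(zip(df.columns, row))
        mz = _parse_float(rec[colmap["mz"]], path, line_no, "mz")
        raw_charge = rec[colmap["charge"]]
        if raw_charge is None or (isinstance(raw_charge, float) and math.isnan(raw_charge)) \
                or str(raw_charge).strip() == "":
            charge = None
        else:
            z = _parse_float(raw_charge, path, line_no, "charge")
            if z != int(z):
                raise ParseError(f"{path}: line {line_no}: non-integer charge {raw_charge!r}")
            charge = int(z)
        intensity = _parse_float(rec[colmap["intensity"]], path, line_no, "intensity")
        mt = _parse_float(rec[colmap["migration_time"]], path, line_no, "migration_time")
        if not (lo <= mz <= hi):
            dropped += 1
            continue
        peaks.append(IonPeak(mz=mz, charge=charge, intensity=intensity, migration_time=mt))
    if dropped:
        logger.info("read_peaklist(%s): dropped %d peak(s) outside m/z window %s", path, dropped, mz_window)
    logger.info("read_peaklist(%s): %d peaks in, %d kept", path, len(df), len(peaks))
    return peaks


def write_peaklist(peaks: Sequence[IonPeak], path) -> None:
    df = pd.DataFrame(
        {
            "mz": [p.mz for p in peaks],
            "charge": ["" if p.charge is None else p.charge for p in peaks],
            "intensity": [p.intensity for p in peaks],
            "migration_time": [p.migration_time for p in peaks],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_profile_signals(path) -> list[NeutralPeptideSignal]:
    """Read one sample's peptide-signal TSV (mass_da, migration_time_min, amplitude)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    signals = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2
        rec = dict(zip(df.columns, row))
        signals.append(
            NeutralPeptideSignal(
                mass=_parse_float(rec["mass_da"], path, line_no, "mass_da"),
                migration_time=_parse_float(rec["migration_time_min"], path, line_no, "migration_time_min"),
                amplitude=_parse_float(rec["amplitude"], path, line_no, "amplitude"),
            )
        )
    return signals


def write_profile_signals(signals: Sequence[NeutralPeptideSignal], path) -> None:
    pd.DataFrame(
        {
            "mass_da": [s.mass for s in signals],
            "migration_time_min": [s.migration_time for s in signals],
            "amplitude": [s.amplitude for s in signals],
        }
    ).to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    """Cohort metadata TSV: sample_id, group, optional age/sex/egfr."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str, "sex": str})
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicate sample_id(s): {sorted(set(dupes))}")
    return df


def write_metadata(profiles: Sequence[SampleProfile], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in profiles],
            "group": [p.group for p in profiles],
            "age": [p.age for p in profiles],
            "sex": [p.sex for p in profiles],
            "egfr": [p.egfr for p in profiles],
        }
    ).to_csv(path, sep="\t", index=False)


def read_cohort(profiles_dir, metadata_path) -> list[SampleProfile]:
    """Assemble SampleProfiles from a metadata table plus one TSV per sample.

    Profiles come back in metadata row order; every sample_id must have a
    ``<sample_id>.tsv`` under ``profiles_dir``.
    """
    profiles_dir = Path(profiles_dir)
    meta = read_metadata(metadata_path)
    missing = [sid for sid in meta["sample_id"] if not (profiles_dir / f"{sid}.tsv").exists()]
    if missing:
        raise MissingDataError(f"no profile file for sample_id(s): {missing}")
    profiles = []
    for row in meta.itertuples(index=False):
        rec = row._asdict()
        signals = read_profile_signals(profiles_dir / f"{rec['sample_id']}.tsv")
        age = rec.get("age")
        egfr = rec.get("egfr")
        profiles.append(
            SampleProfile(
                sample_id=rec["sample_id"],
                group=rec["group"],
                signals=signals,
                age=None if age is None or (isinstance(age, float) and math.isnan(age)) else float(age),
                sex=rec.get("sex"),
                egfr=None if egfr is None or (isinstance(egfr, float) and math.isnan(egfr)) else float(egfr),
            )
        )
    logger.info("read_cohort: %d profiles from %s", len(profiles), profiles_dir)
    return profiles


def write_matrix(matrix: AmplitudeMatrix, path) -> None:
    """Write the amplitude matrix as TSV: sample_id column + one column per peptide."""
    out = matrix.amplitudes.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_matrix(path, metadata_path=None) -> AmplitudeMatrix:
    """Read an amplitude matrix TSV; optionally attach groups from metadata."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id", float_precision="round_trip")
    groups = None
    if metadata_path is not None:
        meta = read_metadata(metadata_path)
        groups = meta.set_index("sample_id")["group"]
    return AmplitudeMatrix(df, groups)


def read_sequenced_peptides(path) -> list[SequencedPeptide]:
    """TSV with columns sequence, neutral_mass, protein_symbol."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "protein_symbol": str})
    for col in ("sequence", "neutral_mass", "protein_symbol"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return [
        SequencedPeptide(r.sequence, float(r.neutral_mass), r.protein_symbol)
        for r in df.itertuples(index=False)
    ]
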