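"""Synthetic CE-MS cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
catalogue of urinary peptides with log-normal amplitudes, per-peptide
Bernoulli detection (amplitude 0 = not detected), a block of high-frequency
low-variance housekeeping peptides, case/control marker peptides with a
multiplicative effect in randomized direction, a per-sample dilution factor
(urine concentration varies several-fold between voids), and — through
:func:`simulate_ion_peaks` — charge-ladder ion peaks with ppm-scale mass
noise inside the instrument's m/z window.

All randomness flows through one ``numpy.random.default_rng`` (PCG64, a
named portable generator): identical seed, identical cohort, on any OS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .types import (
    DEFAULT_MZ_WINDOW,
    PROTON_MASS,
    AmplitudeMatrix,
    IonPeak,
    NeutralPeptideSignal,
    SampleProfile,
    TruthRecord,
)

logger = logging.getLogger("peptipanel")


@dataclass
class SimConfig:
    """Parameters of one simulated cohort.

    Defaults mirror the discovery design: 22 cases vs 22 controls, a
    200-peptide catalogue containing 29 housekeeping peptides and 20 true
    markers at 4-fold effect.
    """

    n_case: int = 22
    n_control: int = 22
    n_peptides: int = 200
    n_markers: int = 20
    effect_fold: float = 4.0
    n_housekeeping: int = 29
    #: background per-peptide detection probability drawn uniform over this range
    detect_freq_background: tuple[float, float] = (0.2, 0.95)
    #: markers must be detectable to be discoverable; drawn uniform over this range
    detect_freq_marker: tuple[float, float] = (0.85, 1.0)
    detect_freq_housekeeping: float = 0.98
    amplitude_meanlog: float = 7.0
    amplitude_sdlog: float = 0.8
    #: peptide-to-peptide spread of baseline meanlog
    baseline_spread: float = 1.0
    housekeeping_sdlog: float = 0.25
    mass_range: tuple[float, float] = (800.0, 15000.0)
    mt_range: tuple[float, float] = (10.0, 45.0)
    ppm_noise: float = 5.0
    mt_noise_min: float = 0.05
    dilution_range: tuple[float, float] = (0.25, 4.0)
    case_group: str = "case"
    control_group: str = "control"
    seed: int = 0
    #: seed for the peptide catalogue (masses, MTs, roles, detection
    #: probabilities, effect directions).  A validation cohort drawn from the
    #: same population as a discovery cohort shares its catalogue_seed while
    #: using a fresh sampling seed; None means "use ``seed``".
    catalogue_seed: Optional[int] = None

    def validate(self) -> None:
        if min(self.n_case, self.n_control, self.n_peptides) < 0 or self.n_markers < 0:
            raise ConfigError("counts must be >= 0")
        if self.effect_fold < 1:
            raise ConfigError(f"effect_fold must be >= 1, got {self.effect_fold}")
        if self.n_markers > self.n_peptides - self.n_housekeeping:
            raise ConfigError(
                f"n_markers={self.n_markers} exceeds the {self.n_peptides - self.n_housekeeping} "
                "non-housekeeping peptides available"
            )
        if self.n_housekeeping > self.n_peptides:
            raise ConfigError("n_housekeeping exceeds n_peptides")
        # housekeeping CV(log-amplitude) must be at most half the background's
        if self.housekeeping_sdlog > 0.5 * self.amplitude_sdlog:
            raise ConfigError("housekeeping_sdlog must be <= half amplitude_sdlog")


@dataclass
class SimulatedCohort:
    """Full generator output, including internals the TSV contract omits."""

    profiles: list[SampleProfile]
    truth: list[TruthRecord]
    #: samples x peptides amplitudes before per-sample dilution (0 = not detected)
    base_amplitudes: pd.DataFrame
    dilution_factors: pd.Series
    config: SimConfig

    @property
    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.truth]).set_index("peptide_id")


def _draw_separated_masses(rng: np.random.Generator, n: int,
                           mass_range: tuple[float, float],
                           min_rel_gap: float = 5e-4) -> np.ndarray:
    """Log-uniform masses with adjacent relative gaps above min_rel_gap.

    The gap (default 500 ppm, 10x the cross-sample clustering tolerance)
    guarantees distinct catalogue peptides can never merge into one
    consensus cluster.
    """
    lo, hi = math.log(mass_range[0]), math.log(mass_range[1])
    masses = np.sort(np.exp(rng.uniform(lo, hi, n)))
    for _ in range(200):
        rel_gap = np.diff(masses) / masses[:-1]
        bad = np.where(rel_gap < min_rel_gap)[0]
        if bad.size == 0:
            return masses
        masses[bad + 1] = np.exp(rng.uniform(lo, hi, bad.size))
        masses = np.sort(masses)
    raise ConfigError("could not place peptide masses with required separation")


def simulate_cohort_full(config: SimConfig) -> SimulatedCohort:
    """Generate a cohort and return profiles, truth and generator internals."""
    config.validate()
    cat_seed = config.seed if config.catalogue_seed is None else config.catalogue_seed
    # separate streams: the catalogue is a property of the peptide population,
    # the sample draws of one cohort; distinct spawn keys keep them independent
    # even when both seeds coincide
    rng_cat = np.random.default_rng([0, cat_seed])
    rng = np.random.default_rng([1, config.seed])
    n_pep = config.n_peptides
    n_samples = config.n_case + config.n_control

    peptide_ids = [f"T{i + 1:04d}" for i in range(n_pep)]
    masses = _draw_separated_masses(rng_cat, n_pep, config.mass_range)
    mts = rng_cat.uniform(*config.mt_range, n_pep)

    is_hk = np.zeros(n_pep, dtype=bool)
    is_hk[:config.n_housekeeping] = True
    non_hk = np.where(~is_hk)[0]
    marker_idx = rng_cat.choice(non_hk, size=config.n_markers, replace=False)
    is_marker = np.zeros(n_pep, dtype=bool)
    is_marker[marker_idx] = True
    # fair coin per marker: positive fold = up in cases
    direction = np.ones(n_pep)
    direction[marker_idx] = rng_cat.choice([-1.0, 1.0], size=config.n_markers)

    detect_p = rng_cat.uniform(*config.detect_freq_background, n_pep)
    detect_p[is_marker] = rng_cat.uniform(*config.detect_freq_marker, config.n_markers)
    detect_p[is_hk] = config.detect_freq_housekeeping

    baseline = config.amplitude_meanlog + rng_cat.uniform(
        -config.baseline_spread, config.baseline_spread, n_pep
    )
    sdlog = np.full(n_pep, config.amplitude_sdlog)
    sdlog[is_hk] = config.housekeeping_sdlog

    group = np.array([config.case_group] * config.n_case + [config.control_group] * config.n_control)
    is_case = group == config.case_group

    # case-group meanlog shifted by ±ln(effect_fold): the log-normal mean then
    # scales by exactly effect_fold relative to controls
    shift = np.zeros((n_samples, n_pep))
    log_fold = math.log(config.effect_fold)
    shift[np.ix_(is_case, is_marker)] = direction[is_marker] * log_fold

    log_amp = rng.normal(baseline[None, :] + shift, sdlog[None, :], size=(n_samples, n_pep))
    detected = rng.random((n_samples, n_pep)) < detect_p[None, :]
    base = np.where(detected, np.exp(log_amp), 0.0)

    dilution = np.exp(rng.uniform(math.log(config.dilution_range[0]),
                                  math.log(config.dilution_range[1]), n_samples))

    mass_obs = masses[None, :] * (1.0 + rng.normal(0.0, config.ppm_noise * 1e-6, (n_samples, n_pep)))
    mt_obs = mts[None, :] + rng.normal(0.0, config.mt_noise_min, (n_samples, n_pep))

    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    ages = rng.uniform(2.0, 18.0, n_samples)
    sexes = rng.choice(["F", "M"], n_samples)
    egfrs = rng.normal(100.0, 25.0, n_samples).clip(10.0, 180.0)

    profiles = []
    for i in range(n_samples):
        signals = [
            NeutralPeptideSignal(
                mass=float(mass_obs[i, j]),
                migration_time=float(mt_obs[i, j]),
                amplitude=float(base[i, j] * dilution[i]),
            )
            for j in range(n_pep)
            if detected[i, j]
        ]
        profiles.append(
            SampleProfile(
                sample_id=sample_ids[i],
                group=str(group[i]),
                signals=signals,
                age=round(float(ages[i]), 1),
                sex=str(sexes[i]),
                egfr=round(float(egfrs[i]), 1),
            )
        )

    truth = [
        TruthRecord(
            peptide_id=peptide_ids[j],
            is_marker=bool(is_marker[j]),
            true_effect_fold=float(direction[j] * (config.effect_fold if is_marker[j] else 1.0)),
            is_housekeeping=bool(is_hk[j]),
            true_mass=float(masses[j]),
            true_mt=float(mts[j]),
        )
        for j in range(n_pep)
    ]

    logger.info(
        "simulate_cohort: %d samples (%d case / %d control), %d peptides "
        "(%d housekeeping, %d markers)",
        n_samples, config.n_case, config.n_control, n_pep,
        config.n_housekeeping, config.n_markers,
    )
    return SimulatedCohort(
        profiles=profiles,
        truth=truth,
        base_amplitudes=pd.DataFrame(base, index=sample_ids, columns=peptide_ids),
        dilution_factors=pd.Series(dilution, index=sample_ids, name="dilution"),
        config=config,
    )


def simulate_cohort(config: SimConfig) -> tuple[list[SampleProfile], list[TruthRecord]]:
    """Generate a cohort; returns (profiles, truth records)."""
    sim = simulate_cohort_full(config)
    return sim.profiles, sim.truth


def simulate_ion_peaks(
    profile: SampleProfile,
    charges: Sequence[int],
    ppm_noise: float,
    seed: int,
    mz_window: tuple[float, float] = DEFAULT_MZ_WINDOW,
    charge_fractions: Optional[Sequence[float]] = None,
) -> list[IonPeak]:
    """Forward model: explode neutral signals into multi-charge ion peaks.

    For each signal of mass M and charge z with (M + z*proton)/z inside the
    m/z window, one peak is emitted at that m/z perturbed by Gaussian ppm
    noise.  The signal amplitude is split across the emitted charges by
    fixed fractions summing to 1 (equal by default), so total intensity is
    conserved; migration time is preserved.
    """
    charges = sorted(set(int(z) for z in charges))
    if not charges or min(charges) < 1:
        raise ConfigError("charges must be a non-empty set of integers >= 1")
    if charge_fractions is not None:
        if len(charge_fractions) != len(charges):
            raise ConfigError("charge_fractions must align with charges")
        fractions = {z: f for z, f in zip(charges, charge_fractions)}
    else:
        fractions = {z: 1.0 for z in charges}

    rng = np.random.default_rng(seed)
    lo, hi = mz_window
    peaks = []
    for sig in profile.signals:
        emitted = []
        for z in charges:
            mz = (sig.mass + z * PROTON_MASS) / z
            if lo <= mz <= hi:
                emitted.append((z, mz))
        if not emitted:
            continue
        total_frac = sum(fractions[z] for z, _ in emitted)
        for z, mz in emitted:
            noisy = mz * (1.0 + rng.normal(0.0, ppm_noise * 1e-6)) if ppm_noise > 0 else mz
            peaks.append(
                IonPeak(
                    mz=noisy,
                    charge=z,
                    intensity=sig.amplitude * fractions[z] / total_frac,
                    migration_time=sig.migration_time,
                )
            )
    return peaks
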