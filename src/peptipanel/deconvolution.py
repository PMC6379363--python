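"""Charge-state deconvolution of ion-peak lists.

A peptide of neutral mass M observed at charge z appears at
m/z = (M + z * 1.00728) / z; one molecule therefore produces a ladder of
peaks across charge states.  Deconvolution inverts this: peaks whose
hypothesized neutral masses agree within a ppm tolerance and whose CE
migration times agree within a minute tolerance are grouped into a single
neutral-mass signal.

Algorithm (deterministic, greedy):

1. For every peak with known charge z, the neutral mass is z*(mz - proton);
   for unknown charge, every z in 1..charge_max is hypothesized.
2. Hypotheses are sorted by mass and clustered against the running
   intensity-weighted mean mass (ppm tolerance) and mean migration time.
3. Candidate groups are accepted in preference order — groups supported by
   >=2 distinct charge states first, then higher summed intensity, then
   lower mass — each peak being explained exactly once.
4. Each accepted group yields one signal: intensity-weighted mean mass and
   migration time, amplitude = summed intensity.  An unknown-charge
   singleton is reported as a charge-1 signal flagged low-confidence.

Total intensity is conserved: every input peak lands in exactly one group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import ConfigError
from .types import PROTON_MASS, IonPeak, NeutralPeptideSignal

logger = logging.getLogger("peptipanel")


@dataclass
class _Hypothesis:
    peak_index: int
    charge: int
    charge_known: bool
    mass: float
    intensity: float
    mt: float


@dataclass
class _Group:
    members: list[_Hypothesis] = field(default_factory=list)
    sum_int: float = 0.0
    sum_int_mass: float = 0.0
    sum_int_mt: float = 0.0

    def add(self, h: _Hypothesis) -> None:
        self.members.append(h)
        self.sum_int += h.intensity
        self.sum_int_mass += h.intensity * h.mass
        self.sum_int_mt += h.intensity * h.mt

    @property
    def mean_mass(self) -> float:
        return self.sum_int_mass / self.sum_int

    @property
    def mean_mt(self) -> float:
        return self.sum_int_mt / self.sum_int

    @property
    def n_charges(self) -> int:
        return len({m.charge for m in self.members})


def deconvolute(
    peaks: Sequence[IonPeak],
    charge_max: int = 6,
    mass_tol_ppm: float = 25.0,
    mt_tol_min: float = 0.5,
) -> list[NeutralPeptideSignal]:
    """Collapse multi-charge ion peaks into neutral-mass peptide signals."""
    if charge_max < 1:
        raise ConfigError(f"charge_max must be >= 1, got {charge_max}")
    if mass_tol_ppm <= 0 or mt_tol_min <= 0:
        raise ConfigError("tolerances must be > 0")
    if not peaks:
        return []

    # 1. expand charge hypotheses
    hyps: list[_Hypothesis] = []
    for i, p in enumerate(peaks):
        if p.charge is not None:
            hyps.append(_Hypothesis(i, p.charge, True, p.neutral_mass(), p.intensity, p.migration_time))
        else:
            for z in range(1, charge_max + 1):
                m = z * (p.mz - PROTON_MASS)
                if m > 0:
                    hyps.append(_Hypothesis(i, z, False, m, p.intensity, p.migration_time))

    # 2. cluster hypotheses, sorted by mass (ties broken by peak order for
    # determinism); a hypothesis joins the most recent open group whose running
    # weighted-mean mass and MT both match, else opens a new group
    hyps.sort(key=lambda h: (h.mass, h.peak_index, h.charge))
    groups: list[_Group] = []
    for h in hyps:
        placed = False
        for g in reversed(groups):
            mm = g.mean_mass
            if h.mass - mm > 3 * mass_tol_ppm * 1e-6 * mm:
                break  # sorted by mass: earlier groups are only farther away
            if abs(h.mass - mm) <= mass_tol_ppm * 1e-6 * mm and abs(h.mt - g.mean_mt) <= mt_tol_min:
                g.add(h)
                placed = True
                break
        if not placed:
            g = _Group()
            g.add(h)
            groups.append(g)

    # 3. accept groups in preference order, explaining each peak exactly once
    order = sorted(
        range(len(groups)),
        key=lambda k: (
            0 if groups[k].n_charges >= 2 else 1,
            -groups[k].sum_int,
            groups[k].mean_mass,
        ),
    )
    assigned: set[int] = set()
    signals: list[NeutralPeptideSignal] = []
    for k in order:
        members = [m for m in groups[k].members if m.peak_index not in assigned]
        if not members:
            continue
        assigned.update(m.peak_index for m in members)
        total = sum(m.intensity for m in members)
        if len(members) == 1 and not members[0].charge_known:
            # unknown-charge singleton: report at charge 1, low confidence
            p = peaks[members[0].peak_index]
            signals.append(
                NeutralPeptideSignal(
                    mass=p.mz - PROTON_MASS,
                    migration_time=p.migration_time,
                    amplitude=p.intensity,
                    low_confidence=True,
                )
            )
            continue
        signals.append(
            NeutralPeptideSignal(
                mass=sum(m.intensity * m.mass for m in members) / total,
                migration_time=sum(m.intensity * m.mt for m in members) / total,
                amplitude=total,
            )
        )

    signals.sort(key=lambda s: (s.mass, s.migration_time))
    logger.info("deconvolute: %d peaks in, %d signals out", len(peaks), len(signals))
    return signals
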