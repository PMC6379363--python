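"""End-to-end orchestration of the synthetic discovery/validation study.

Runs the whole funnel on generated cohorts with known ground truth:
simulate a discovery cohort, cluster signals into the consensus catalogue,
select housekeeping peptides and normalize, discover the differential panel,
train the SVM and pick the CV cutoff, then freeze everything and score an
independently sampled validation cohort drawn from the same peptide
population.  Used by the test suite and the reproduction script; also a
worked example of how the library pieces fit together.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import PipelineConfig
from .evaluation import EvalReport
from .matching import cluster_peptides, map_to_catalogue
from .model import PanelModel, PanelResults
from .normalization import NormalizationReference, normalize_matrix, select_housekeeping
from .simulate import SimConfig, SimulatedCohort, simulate_cohort_full
from .types import AmplitudeMatrix, ConsensusPeptide

logger = logging.getLogger("peptipanel")


@dataclass
class StudyResult:
    """Everything the synthetic study produces, with truth-based diagnostics."""

    discovery: SimulatedCohort
    consensus: list[ConsensusPeptide]
    reference: NormalizationReference
    discovery_matrix: AmplitudeMatrix  # normalized
    results: PanelResults
    truth_map: dict[str, str]  # generator peptide id -> consensus peptide id
    marker_recovery: float  # fraction of true markers present in the panel
    panel_false_fraction: float  # fraction of the panel that is not a true marker
    cv_report: EvalReport
    validation: Optional[SimulatedCohort] = None
    validation_matrix: Optional[AmplitudeMatrix] = None
    validation_report: Optional[EvalReport] = None


def match_truth_to_consensus(
    truth, consensus: list[ConsensusPeptide], max_ppm: float = 50.0
) -> dict[str, str]:
    """Map generator peptide ids to consensus ids by nearest mass within ppm."""
    masses = np.array([c.reference_mass for c in consensus])
    out = {}
    for t in truth:
        k = int(np.argmin(np.abs(masses - t.true_mass)))
        if abs(masses[k] - t.true_mass) / t.true_mass <= max_ppm * 1e-6:
            out[t.peptide_id] = consensus[k].peptide_id
    return out


def run_synthetic_study(
    seed: int = 1,
    discovery_config: Optional[SimConfig] = None,
    validation_config: Optional[SimConfig] = None,
    pipeline_config: Optional[PipelineConfig] = None,
    with_validation: bool = True,
) -> StudyResult:
    """Run the full discovery (+ optional validation) study at one seed.

    The default design mirrors the study: a 22 vs 22 discovery cohort over a
    200-peptide catalogue (29 housekeeping, 20 markers at 4-fold), and a
    24 vs 20 validation cohort sampled independently from the same catalogue.
    """
    cfg = pipeline_config or PipelineConfig()
    dconf = discovery_config or SimConfig(seed=seed)
    sim = simulate_cohort_full(dconf)

    consensus, raw_matrix = cluster_peptides(
        sim.profiles, cfg.cluster_mass_tol_ppm, cfg.cluster_mt_tol_min
    )
    reference = select_housekeeping(raw_matrix, cfg.n_housekeeping, cfg.housekeeping_min_freq)
    norm_matrix, _ = normalize_matrix(raw_matrix, reference, cfg.min_detected_housekeeping)

    model = PanelModel(norm_matrix, case_label=dconf.case_group, config=cfg)
    results = model.fit(seed=seed)

    truth_map = match_truth_to_consensus(sim.truth, consensus, cfg.cluster_mass_tol_ppm)
    marker_ids = {
        truth_map[t.peptide_id] for t in sim.truth if t.is_marker and t.peptide_id in truth_map
    }
    panel = set(results.panel_ids)
    n_markers = sum(t.is_marker for t in sim.truth)
    marker_recovery = len(marker_ids & panel) / n_markers if n_markers else float("nan")
    panel_false_fraction = len(panel - marker_ids) / len(panel) if panel else 0.0

    out = StudyResult(
        discovery=sim,
        consensus=consensus,
        reference=reference,
        discovery_matrix=norm_matrix,
        results=results,
        truth_map=truth_map,
        marker_recovery=marker_recovery,
        panel_false_fraction=panel_false_fraction,
        cv_report=results.cv_report(),
    )
    if not with_validation:
        return out

    vconf = validation_config or dataclasses.replace(
        dconf, n_case=24, n_control=20, seed=seed + 1000, catalogue_seed=dconf.seed
    )
    vsim = simulate_cohort_full(vconf)
    vraw = map_to_catalogue(vsim.profiles, consensus, cfg.cluster_mass_tol_ppm, cfg.cluster_mt_tol_min)
    vnorm, _ = normalize_matrix(vraw, reference, cfg.min_detected_housekeeping)
    out.validation = vsim
    out.validation_matrix = vnorm
    out.validation_report = results.evaluate(
        vnorm, [p.group for p in vsim.profiles], "validation"
    )
    return out
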