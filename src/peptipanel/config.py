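"""Pipeline configuration: every tolerance and threshold in one document.

A single JSON file drives the CLI; library callers pass the dataclass (or
individual keyword arguments) directly.  Defaults follow the study design:
29 housekeeping peptides present in >=90% of samples, a 70% detection
frequency threshold for the differential comparison, Benjamini–Hochberg
alpha 0.05, the instrument window m/z 350–3000, and a ±5 ppm gate for
sequence annotation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class PipelineConfig:
    # instrument / deconvolution
    mz_window: tuple[float, float] = (350.0, 3000.0)
    charge_max: int = 6
    deconv_mass_tol_ppm: float = 25.0
    deconv_mt_tol_min: float = 0.5
    # cross-sample matching
    cluster_mass_tol_ppm: float = 50.0
    cluster_mt_tol_min: float = 0.5
    # sequence annotation
    annotate_max_ppm: float = 5.0
    annotate_mt_window_min: float = 2.0
    # normalization
    n_housekeeping: int = 29
    housekeeping_min_freq: float = 0.90
    min_detected_housekeeping: int = 15
    # differential discovery
    freq_threshold: float = 0.70
    alpha: float = 0.05
    wilcoxon_mode: str = "auto"
    # classifier
    svm_kernel: str = "rbf"
    svm_c: float = 1.0
    svm_gamma: str | float = "median"
    cv_scheme: str = "loo"
    cv_folds: int = 10
    cutoff_strategy: str = "youden"
    cutoff: float | None = None  # user-supplied override, e.g. the study's 0.30

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.mz_window, list):
            cfg.mz_window = tuple(cfg.mz_window)
        return cfg

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def default_config() -> PipelineConfig:
    return PipelineConfig()
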