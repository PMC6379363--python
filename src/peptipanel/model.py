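"""Model/Results facade over the discovery-and-classification core.

``PanelModel`` is built from a normalized amplitude matrix with group
labels; ``fit()`` runs the discovery funnel (frequency filter, Wilcoxon,
Benjamini–Hochberg), trains the panel SVM, computes leave-one-out CV scores
and selects the score cutoff, returning a ``PanelResults`` that carries the
panel table, the frozen classifier, CV diagnostics and a ``summary()``.
New cohorts are scored through ``PanelResults.predict`` / ``evaluate``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .classifier import (
    ClassifierModel,
    SVMHyperparams,
    cross_validated_scores,
    select_cutoff,
    train_classifier,
)
from .config import PipelineConfig
from .differential import DifferentialConfig, discover_panel, panel_to_frame
from .errors import ValidationError
from .evaluation import EvalReport, evaluate_scores, roc_auc
from .types import AmplitudeMatrix, ScoreResult

logger = logging.getLogger("peptipanel")


class PanelModel:
    """Biomarker-panel discovery + classification model.

    Parameters
    ----------
    matrix : AmplitudeMatrix
        Normalized samples x peptides amplitudes (0 = not detected).
    labels : pd.Series, optional
        Group label per sample; defaults to ``matrix.groups``.
    case_label : str
        Which group is the positive (disease) class.
    config : PipelineConfig, optional
        Thresholds and hyperparameters; defaults follow the study design.
    """

    def __init__(
        self,
        matrix: AmplitudeMatrix,
        labels: Optional[pd.Series] = None,
        case_label: str = "case",
        config: Optional[PipelineConfig] = None,
    ):
        self.matrix = matrix
        labels = labels if labels is not None else matrix.groups
        if labels is None:
            raise ValidationError("group labels required (on matrix or as argument)")
        self.labels = labels.reindex(matrix.amplitudes.index).astype(str)
        if self.labels.isna().any():
            raise ValidationError("every sample needs a group label")
        self.case_label = case_label
        self.config = config or PipelineConfig()

    @classmethod
    def from_dataframe(
        cls,
        amplitudes: pd.DataFrame,
        groups: pd.Series,
        case_label: str = "case",
        config: Optional[PipelineConfig] = None,
    ) -> "PanelModel":
        return cls(AmplitudeMatrix(amplitudes, groups), None, case_label, config)

    def fit(self, seed: int = 0) -> "PanelResults":
        cfg = self.config
        control_label = next(
            u for u in sorted(self.labels.unique()) if u != self.case_label
        )
        entries = discover_panel(
            self.matrix,
            self.labels,
            DifferentialConfig(cfg.freq_threshold, cfg.alpha, cfg.wilcoxon_mode),
            case_label=self.case_label,
            control_label=control_label,
        )
        if not entries:
            raise ValidationError(
                "no differential peptides at the configured thresholds; nothing to model"
            )
        panel_ids = [e.peptide_id for e in entries]
        hp = SVMHyperparams(kernel=cfg.svm_kernel, c=cfg.svm_c, gamma=cfg.svm_gamma)
        classifier = train_classifier(
            self.matrix, self.labels, panel_ids, hp, seed=seed, case_label=self.case_label
        )
        cv = cross_validated_scores(
            self.matrix, self.labels, panel_ids, hp,
            scheme=cfg.cv_scheme, seed=seed, n_folds=cfg.cv_folds,
            case_label=self.case_label,
        )
        cutoff = (
            cfg.cutoff
            if cfg.cutoff is not None
            else select_cutoff(cv, self.labels, cfg.cutoff_strategy, self.case_label)
        )
        classifier.cutoff = float(cutoff)
        return PanelResults(self, entries, classifier, cv, seed)


class PanelResults:
    """Fitted panel: discovery table, frozen classifier, CV diagnostics."""

    def __init__(self, model: PanelModel, entries, classifier: ClassifierModel,
                 cv_scores: list[ScoreResult], seed: int):
        self.model = model
        self.entries = entries
        self.classifier = classifier
        self.cv_scores = cv_scores
        self.seed = seed

    @property
    def panel(self) -> pd.DataFrame:
        return panel_to_frame(self.entries)

    @property
    def panel_ids(self) -> list[str]:
        return list(self.classifier.panel_ids)

    @property
    def cutoff(self) -> float:
        return float(self.classifier.cutoff)

    def cv_report(self) -> EvalReport:
        """Discovery-cohort performance of the CV scores at the chosen cutoff."""
        truth = self.model.labels.loc[[r.sample_id for r in self.cv_scores]]
        preds = [
            ScoreResult(
                r.sample_id,
                r.score,
                self.classifier.case_label if r.score >= self.cutoff else self.classifier.control_label,
            )
            for r in self.cv_scores
        ]
        return evaluate_scores(preds, truth.tolist(), self.model.case_label, "discovery (CV)")

    def predict(self, matrix: AmplitudeMatrix) -> list[ScoreResult]:
        """Score new samples with the frozen classifier and cutoff."""
        return self.classifier.score_samples(matrix)

    def evaluate(
        self, matrix: AmplitudeMatrix, truth: Sequence[str], cohort_label: str = ""
    ) -> EvalReport:
        return evaluate_scores(self.predict(matrix), list(truth),
                               self.model.case_label, cohort_label)

    def summary(self) -> str:
        rep = self.cv_report()
        df = self.panel
        top = df.head(10).to_string(index=False, float_format=lambda v: f"{v:.3g}")
        lines = [
            "Peptide panel classifier",
            "=" * 60,
            f"samples: {self.model.matrix.n_samples} "
            f"({(self.model.labels == self.model.case_label).sum()} {self.model.case_label} / "
            f"{(self.model.labels != self.model.case_label).sum()} other)",
            f"peptides in matrix: {self.model.matrix.n_peptides}",
            f"panel size (adjusted p < {self.model.config.alpha}): {len(self.entries)}",
            f"score cutoff ({self.model.config.cutoff_strategy}"
            f"{', user-supplied' if self.model.config.cutoff is not None else ''}): "
            f"{self.cutoff:.4f}",
            "",
            "Cross-validated discovery performance:",
            rep.summary(),
            "",
            f"Top panel peptides (of {len(df)}):",
            top,
        ]
        return "\n".join(lines)
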