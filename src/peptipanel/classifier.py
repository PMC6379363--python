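"""SVM panel classifier with cross-validated cutoff selection.

The panel peptides' amplitudes (log(1+a) transformed, standardized with
training statistics) feed a support-vector machine whose continuous decision
value is the classification score, oriented so that higher = more case-like.
The score cutoff is not a constant of the method: it is chosen from complete
leave-one-out cross-validation scores on the discovery cohort (Youden's J by
default), then frozen into the model for validation-phase scoring.

Models serialize to JSON — panel ids, transform tag, hyperparameters,
standardization vectors, support-vector coefficients, cutoff and a training
fingerprint — and a deserialized model scores new samples by evaluating the
RBF decision function directly from the stored support vectors, so loading
never refits anything.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.svm import SVC

from .errors import ConfigError, ValidationError
from .types import AmplitudeMatrix, ScoreResult

logger = logging.getLogger("peptipanel")


@dataclass
class SVMHyperparams:
    kernel: str = "rbf"
    c: float = 1.0
    gamma: str | float = "median"  # "median" = median-pairwise-distance heuristic

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ConfigError(f"unsupported kernel {self.kernel!r}")
        if self.c <= 0:
            raise ConfigError("C must be > 0")


@dataclass
class ClassifierModel:
    """A trained panel classifier, fully described by plain arrays."""

    panel_ids: list[str]
    transform: str  # "log1p"
    hyperparams: SVMHyperparams
    feature_mean: np.ndarray
    feature_std: np.ndarray
    support_vectors: np.ndarray  # in standardized feature space
    dual_coef: np.ndarray
    intercept: float
    gamma_value: float  # resolved numeric gamma (unused for linear kernel)
    case_label: str
    control_label: str
    cutoff: Optional[float] = None
    training_fingerprint: str = ""

    # -- scoring ---------------------------------------------------------
    def _transform(self, matrix: AmplitudeMatrix) -> np.ndarray:
        missing = [p for p in self.panel_ids if p not in matrix.amplitudes.columns]
        if missing:
            raise ValidationError(
                f"panel peptide column(s) missing from matrix: {missing[:5]}"
                f"{'...' if len(missing) > 5 else ''} (a zero amplitude is allowed; "
                "a missing column is not)"
            )
        X = np.log1p(matrix.amplitudes[self.panel_ids].to_numpy(dtype=float))
        return (X - self.feature_mean) / self.feature_std

    def decision_values(self, matrix: AmplitudeMatrix) -> np.ndarray:
        """Continuous classification scores, higher = more case-like."""
        Z = self._transform(matrix)
        if self.hyperparams.kernel == "rbf":
            d2 = ((Z[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=2)
            K = np.exp(-self.gamma_value * d2)
        else:
            K = Z @ self.support_vectors.T
        return K @ self.dual_coef + self.intercept

    def score_samples(self, matrix: AmplitudeMatrix) -> list[ScoreResult]:
        """Score new samples with the frozen model; case iff score >= cutoff."""
        if self.cutoff is None:
            raise ValidationError("model has no cutoff; call select_cutoff or set one")
        scores = self.decision_values(matrix)
        return [
            ScoreResult(
                sample_id=sid,
                score=float(s),
                predicted=self.case_label if s >= self.cutoff else self.control_label,
            )
            for sid, s in zip(matrix.sample_ids, scores)
        ]

    # -- persistence -----------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "panel_ids": self.panel_ids,
            "transform": self.transform,
            "hyperparams": {"kernel": self.hyperparams.kernel, "c": self.hyperparams.c,
                            "gamma": self.hyperparams.gamma},
            "feature_mean": self.feature_mean.tolist(),
            "feature_std": self.feature_std.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "gamma_value": self.gamma_value,
            "case_label": self.case_label,
            "control_label": self.control_label,
            "cutoff": self.cutoff,
            "training_fingerprint": self.training_fingerprint,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ClassifierModel":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            doc = json.loads(Path(source).read_text())
        else:
            doc = json.loads(source)
        hp = doc["hyperparams"]
        return cls(
            panel_ids=list(doc["panel_ids"]),
            transform=doc["transform"],
            hyperparams=SVMHyperparams(kernel=hp["kernel"], c=hp["c"], gamma=hp["gamma"]),
            feature_mean=np.array(doc["feature_mean"]),
            feature_std=np.array(doc["feature_std"]),
            support_vectors=np.array(doc["support_vectors"]),
            dual_coef=np.array(doc["dual_coef"]),
            intercept=float(doc["intercept"]),
            gamma_value=float(doc["gamma_value"]),
            case_label=doc["case_label"],
            control_label=doc["control_label"],
            cutoff=doc["cutoff"],
            training_fingerprint=doc["training_fingerprint"],
        )


def _resolve_gamma(Z: np.ndarray, gamma: str | float) -> float:
    if isinstance(gamma, (int, float)):
        if gamma <= 0:
            raise ConfigError("gamma must be > 0")
        return float(gamma)
    if gamma != "median":
        raise ConfigError(f"unknown gamma spec {gamma!r}")
    d = pdist(Z)
    d = d[d > 0]
    if d.size == 0:
        return 1.0 / max(Z.shape[1], 1)
    med = float(np.median(d))
    return 1.0 / (2.0 * med * med)


def _fingerprint(X: np.ndarray, y: np.ndarray, seed: int) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    h.update(str(seed).encode())
    return h.hexdigest()[:16]


def train_classifier(
    matrix: AmplitudeMatrix,
    labels: pd.Series,
    panel_ids: Sequence[str],
    hyperparams: Optional[SVMHyperparams] = None,
    seed: int = 0,
    case_label: str = "case",
) -> ClassifierModel:
    """Fit the panel SVM on log(1+a)-transformed, standardized amplitudes.

    Class weights are balanced; the decision value is oriented so cases
    score high.  Deterministic for fixed inputs and seed.
    """
    hyperparams = hyperparams or SVMHyperparams()
    labels = labels.reindex(matrix.amplitudes.index).astype(str)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValidationError(f"need exactly two classes, got {uniq}")
    if case_label not in uniq:
        raise ValidationError(f"case label {case_label!r} not among {uniq}")
    control_label = next(u for u in uniq if u != case_label)
    counts = labels.value_counts()
    if counts.min() < 3:
        raise ValidationError(f"need >= 3 samples per class, got {counts.to_dict()}")

    panel_ids = list(panel_ids)
    missing = [p for p in panel_ids if p not in matrix.amplitudes.columns]
    if missing:
        raise ValidationError(f"panel id(s) absent from matrix: {missing}")

    X = np.log1p(matrix.amplitudes[panel_ids].to_numpy(dtype=float))
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    std = np.where(std > 0, std, 1.0)
    Z = (X - mean) / std
    y = (labels == case_label).astype(int).to_numpy()

    gamma_value = _resolve_gamma(Z, hyperparams.gamma)
    svc = SVC(
        kernel=hyperparams.kernel,
        C=hyperparams.c,
        gamma=gamma_value if hyperparams.kernel == "rbf" else "scale",
        class_weight="balanced",
        random_state=seed,
    )
    svc.fit(Z, y)
    # sklearn orders classes [0, 1]; decision_function > 0 <=> class 1 = case.
    # Recenter the score origin at the midpoint of the two training class-mean
    # decision values: raw SVM offsets drift with class balance (leave-one-out
    # folds are always imbalanced by one), and only recentered scores are
    # comparable across folds and cohorts.
    train_dec = svc.decision_function(Z)
    offset = (train_dec[y == 1].mean() + train_dec[y == 0].mean()) / 2.0
    model = ClassifierModel(
        panel_ids=panel_ids,
        transform="log1p",
        hyperparams=hyperparams,
        feature_mean=mean,
        feature_std=std,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        intercept=float(svc.intercept_[0] - offset),
        gamma_value=gamma_value,
        case_label=case_label,
        control_label=control_label,
        training_fingerprint=_fingerprint(X, y, seed),
    )
    return model


def cross_validated_scores(
    matrix: AmplitudeMatrix,
    labels: pd.Series,
    panel_ids: Sequence[str],
    hyperparams: Optional[SVMHyperparams] = None,
    scheme: str = "loo",
    seed: int = 0,
    n_folds: int = 10,
    case_label: str = "case",
) -> list[ScoreResult]:
    """Cross-validated classification scores; LOO by default.

    Every fold re-derives the transform statistics on its training split, so
    the held-out sample leaks nothing into its own score.  Output order
    equals input sample order.
    """
    labels = labels.reindex(matrix.amplitudes.index).astype(str)
    n = matrix.n_samples
    if scheme == "loo":
        folds = [([j for j in range(n) if j != i], [i]) for i in range(n)]
    elif scheme == "kfold":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        chunks = np.array_split(perm, n_folds)
        folds = [
            (sorted(set(range(n)) - set(c.tolist())), sorted(c.tolist())) for c in chunks if c.size
        ]
    else:
        raise ConfigError(f"unknown CV scheme {scheme!r}")

    scores = np.full(n, np.nan)
    ids = matrix.sample_ids
    for train_idx, test_idx in folds:
        sub = AmplitudeMatrix(matrix.amplitudes.iloc[train_idx], None)
        model = train_classifier(
            sub, labels.iloc[train_idx], panel_ids, hyperparams, seed=seed, case_label=case_label
        )
        held = AmplitudeMatrix(matrix.amplitudes.iloc[test_idx], None)
        scores[test_idx] = model.decision_values(held)

    control_label = next(u for u in sorted(labels.unique()) if u != case_label)
    return [
        ScoreResult(sample_id=ids[i], score=float(scores[i]),
                    predicted=case_label if scores[i] >= 0 else control_label)
        for i in range(n)
    ]


def select_cutoff(
    cv_scores: Sequence[ScoreResult],
    labels: pd.Series,
    strategy: str = "youden",
    case_label: str = "case",
) -> float:
    """Pick the score cutoff from CV scores.

    Candidates are midpoints between adjacent distinct sorted scores;
    ``youden`` maximizes sensitivity + specificity - 1, ``max_accuracy`` the
    raw accuracy.  Ties break toward higher specificity, then lower cutoff.
    """
    if strategy not in ("youden", "max_accuracy"):
        raise ConfigError(f"unknown cutoff strategy {strategy!r}")
    s = np.array([r.score for r in cv_scores])
    y = labels.reindex([r.sample_id for r in cv_scores]).astype(str).to_numpy()
    is_case = y == case_label
    if is_case.all() or (~is_case).all():
        raise ValidationError("both classes must be present in CV scores")
    distinct = np.unique(s)
    if distinct.size < 2:
        raise ValidationError("all CV scores identical; no cutoff is defined")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0

    n_case = is_case.sum()
    n_control = (~is_case).sum()
    best = None
    for c in candidates:
        pred = s >= c
        sens = (pred & is_case).sum() / n_case
        spec = (~pred & ~is_case).sum() / n_control
        obj = sens + spec - 1 if strategy == "youden" else (sens * n_case + spec * n_control) / len(s)
        key = (obj, spec, -c)  # maximize objective, then specificity, then prefer lower cutoff
        if best is None or key > best[0]:
            best = (key, float(c))
    return best[1]
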