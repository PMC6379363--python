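"""SVM training, LOO scores, cutoff selection, serialization, invariants."""

import numpy as np
import pandas as pd
import pytest

from peptipanel import (
    AmplitudeMatrix,
    ClassifierModel,
    SimConfig,
    SVMHyperparams,
    cross_validated_scores,
    select_cutoff,
    simulate_cohort_full,
    train_classifier,
)
from peptipanel.errors import ValidationError
from peptipanel.types import ScoreResult


def _toy(n_per_class=6, sep=5.0, seed=0):
    """Linearly separable 2-feature toy: cases larger on both features."""
    rng = np.random.default_rng(seed)
    case = rng.lognormal(3 + sep / 5, 0.2, (n_per_class, 2))
    ctrl = rng.lognormal(3 - sep / 5, 0.2, (n_per_class, 2))
    amp = pd.DataFrame(np.vstack([case * 10, ctrl]),
                       index=[f"s{i}" for i in range(2 * n_per_class)],
                       columns=["pA", "pB"])
    groups = pd.Series(["case"] * n_per_class + ["control"] * n_per_class,
                       index=amp.index)
    return AmplitudeMatrix(amp, groups), groups


class TestTrain:
    def test_separable_toy_orders_scores(self):
        m, groups = _toy()
        model = train_classifier(m, groups, ["pA", "pB"])
        scores = model.decision_values(m)
        case_scores = scores[(groups == "case").values]
        ctrl_scores = scores[(groups == "control").values]
        assert case_scores.min() > ctrl_scores.max()

    def test_single_class_rejected(self):
        m, groups = _toy()
        all_case = pd.Series("case", index=groups.index)
        with pytest.raises(ValidationError):
            train_classifier(m, all_case, ["pA", "pB"])

    def test_absent_panel_id_rejected(self):
        m, groups = _toy()
        with pytest.raises(ValidationError, match="absent"):
            train_classifier(m, groups, ["pA", "nope"])

    def test_determinism_same_seed_same_scores(self):
        m, groups = _toy(seed=3)
        probe, _ = _toy(seed=9)
        s1 = train_classifier(m, groups, ["pA", "pB"], seed=5).decision_values(probe)
        s2 = train_classifier(m, groups, ["pA", "pB"], seed=5).decision_values(probe)
        assert (s1 == s2).all()

    def test_manual_decision_matches_sklearn(self):
        """Stored support-vector scoring reproduces sklearn's decision_function."""
        from sklearn.svm import SVC

        m, groups = _toy(n_per_class=10, sep=2.0, seed=11)
        model = train_classifier(m, groups, ["pA", "pB"])
        X = np.log1p(m.amplitudes[["pA", "pB"]].to_numpy())
        Z = (X - model.feature_mean) / model.feature_std
        svc = SVC(kernel="rbf", C=1.0, gamma=model.gamma_value, class_weight="balanced")
        y = (groups == "case").astype(int).values
        svc.fit(Z, y)
        dec = svc.decision_function(Z)
        # scores are recentered at the midpoint of the training class means
        expected = dec - (dec[y == 1].mean() + dec[y == 0].mean()) / 2.0
        assert model.decision_values(m) == pytest.approx(expected, abs=1e-10)


class TestCrossValidation:
    def test_loo_produces_one_score_per_sample_in_order(self):
        m, groups = _toy(n_per_class=4)
        cv = cross_validated_scores(m, groups, ["pA", "pB"])
        assert [r.sample_id for r in cv] == m.sample_ids

    def test_no_leakage_from_held_out_label(self):
        """Corrupting sample i's label never changes sample i's CV score."""
        m, groups = _toy(n_per_class=5, seed=2)
        cv = cross_validated_scores(m, groups, ["pA", "pB"])
        corrupted = groups.copy()
        corrupted.iloc[0] = "control" if corrupted.iloc[0] == "case" else "case"
        cv2 = cross_validated_scores(m, corrupted, ["pA", "pB"])
        assert cv2[0].score == cv[0].score

    def test_strong_signal_cohort_cv_auc(self, study):
        """The 22 vs 22 discovery design reaches LOO CV AUC >= 0.95."""
        assert study.cv_report.auc >= 0.95

    def test_pure_noise_cohorts_have_chance_level_auc(self):
        """Mean CV AUC over null seeds sits in [0.4, 0.6]."""
        from peptipanel.evaluation import roc_auc

        aucs = []
        for seed in range(25):
            sim = simulate_cohort_full(
                SimConfig(n_case=10, n_control=10, n_peptides=40, n_markers=0,
                          n_housekeeping=8, detect_freq_background=(0.7, 0.95),
                          seed=4000 + seed)
            )
            groups = pd.Series([p.group for p in sim.profiles],
                               index=sim.base_amplitudes.index)
            m = AmplitudeMatrix(sim.base_amplitudes, groups)
            panel = m.peptide_ids[8:28]  # arbitrary fixed feature set
            cv = cross_validated_scores(m, groups, panel)
            auc, _, _ = roc_auc([r.score for r in cv], groups.tolist(), "case")
            aucs.append(auc)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_stronger_markers_never_lower_case_scores(self):
        """Monotone orientation: amplifying case marker amplitudes raises
        (never lowers) the mean case decision value."""
        m, groups = _toy(n_per_class=8, sep=1.0, seed=13)
        model = train_classifier(m, groups, ["pA", "pB"])
        boosted = m.amplitudes.copy()
        boosted.loc[groups == "case"] *= 3.0
        base_mean = model.decision_values(m)[(groups == "case").values].mean()
        boost_mean = model.decision_values(AmplitudeMatrix(boosted, groups))[
            (groups == "case").values
        ].mean()
        assert boost_mean >= base_mean - 1e-9


class TestCutoff:
    def _scores(self, vals, labels):
        return (
            [ScoreResult(f"s{i}", v, "") for i, v in enumerate(vals)],
            pd.Series(labels, index=[f"s{i}" for i in range(len(vals))]),
        )

    def test_perfect_separation_picks_lowest_optimal_midpoint(self):
        cv, labels = self._scores([-2.0, -1.0, 1.0, 2.0],
                                  ["control", "control", "case", "case"])
        cutoff = select_cutoff(cv, labels)
        # J is maximal on the whole gap; specificity ties; lower cutoff wins
        assert cutoff == pytest.approx(0.0)

    def test_all_identical_scores_error(self):
        cv, labels = self._scores([0.5, 0.5, 0.5, 0.5],
                                  ["control", "control", "case", "case"])
        with pytest.raises(ValidationError):
            select_cutoff(cv, labels)

    def test_one_class_error(self):
        cv, labels = self._scores([0.1, 0.2], ["case", "case"])
        with pytest.raises(ValidationError):
            select_cutoff(cv, labels)

    def test_discovery_cutoff_reaches_085_sens_and_spec(self, study):
        rep = study.cv_report
        assert rep.sensitivity >= 0.85
        assert rep.specificity >= 0.85


class TestScoring:
    def test_cutoff_boundary_is_case(self):
        m, groups = _toy()
        model = train_classifier(m, groups, ["pA", "pB"])
        scores = model.decision_values(m)
        model.cutoff = float(scores[0])
        results = model.score_samples(m)
        assert results[0].predicted == "case"  # score == cutoff -> case

    def test_all_zero_sample_scores_without_error(self):
        m, groups = _toy()
        model = train_classifier(m, groups, ["pA", "pB"])
        model.cutoff = 0.0
        zeros = AmplitudeMatrix(
            pd.DataFrame([[0.0, 0.0]], index=["z"], columns=["pA", "pB"])
        )
        (r,) = model.score_samples(zeros)
        assert np.isfinite(r.score)

    def test_missing_panel_column_distinct_from_zero(self):
        m, groups = _toy()
        model = train_classifier(m, groups, ["pA", "pB"])
        model.cutoff = 0.0
        partial = AmplitudeMatrix(pd.DataFrame([[1.0]], index=["z"], columns=["pA"]))
        with pytest.raises(ValidationError, match="missing"):
            model.score_samples(partial)

    def test_json_round_trip_scores_bit_identical(self, tmp_path):
        m, groups = _toy(n_per_class=7, seed=21)
        model = train_classifier(m, groups, ["pA", "pB"])
        model.cutoff = 0.25
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = ClassifierModel.from_json(path)
        assert (loaded.decision_values(m) == model.decision_values(m)).all()
        assert loaded.cutoff == model.cutoff
        assert loaded.training_fingerprint == model.training_fingerprint
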