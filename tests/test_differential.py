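"""Differential discovery: filter rule, rank test vs brute force, BH, funnel."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peptipanel import (
    AmplitudeMatrix,
    DifferentialConfig,
    SimConfig,
    bh_adjust,
    discover_panel,
    fold_change,
    frequency_filter,
    simulate_cohort_full,
    wilcoxon_rank_sum,
)
from peptipanel.errors import PowerError, ValidationError
from peptipanel.pipeline import match_truth_to_consensus

from oracles import bh_stepup, exact_rank_sum_p


def _matrix_from_detection(case_detected, control_detected):
    """One-peptide matrix with the given detection patterns."""
    n_case, n_control = len(case_detected), len(control_detected)
    amp = pd.DataFrame(
        {"p1": [10.0 if d else 0.0 for d in case_detected + control_detected]},
        index=[f"s{i}" for i in range(n_case + n_control)],
    )
    groups = pd.Series(["case"] * n_case + ["control"] * n_control, index=amp.index)
    return AmplitudeMatrix(amp, groups), groups


class TestFrequencyFilter:
    @pytest.mark.parametrize(
        "case_hits,control_hits,kept",
        [
            (8, 1, True),   # 80% in cases passes
            (6, 6, False),  # 60% in both fails
            (7, 0, True),   # exactly 70%: inclusive boundary
        ],
    )
    def test_seventy_percent_rule(self, case_hits, control_hits, kept):
        m, groups = _matrix_from_detection(
            [i < case_hits for i in range(10)], [i < control_hits for i in range(10)]
        )
        result = frequency_filter(m, groups, threshold=0.7)
        assert (result == ["p1"]) == kept

    def test_unknown_label_rejected(self):
        m, groups = _matrix_from_detection([True] * 5, [True] * 5)
        with pytest.raises(ValidationError, match="unknown group"):
            frequency_filter(m, groups, 0.7, case_label="nope")


class TestWilcoxon:
    def test_textbook_example(self):
        # complete separation of 3 vs 3: exact two-sided p = 2/20
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="exact")
        assert p == pytest.approx(0.1)

    def test_identical_samples_give_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], mode="exact")
        assert p == 1.0

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(size=rng.integers(3, 12))
            y = rng.normal(size=rng.integers(3, 12))
            assert wilcoxon_rank_sum(x, y)[1] == pytest.approx(wilcoxon_rank_sum(y, x)[1])

    def test_exact_p_equals_exhaustive_permutation_all_small_sizes(self):
        """Full equivalence sweep against brute-force enumeration, n,m <= 6."""
        rng = np.random.default_rng(77)
        for n in range(1, 7):
            for m in range(n, 7):
                x = rng.normal(size=n)
                y = rng.normal(size=m)  # continuous draws: no ties
                _, p = wilcoxon_rank_sum(x, y, mode="exact")
                assert p == pytest.approx(exact_rank_sum_p(x, y), abs=1e-12), (n, m)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])

    def test_null_calibration_with_zeros_and_ties(self):
        """Raw p < 0.05 in ~5% of pure-null peptides (zeros enter as values)."""
        sim = simulate_cohort_full(
            SimConfig(n_case=22, n_control=22, n_peptides=1000, n_markers=0,
                      n_housekeeping=29, seed=55)
        )
        amp = sim.base_amplitudes
        groups = np.array([p.group for p in sim.profiles])
        ps = np.array([
            wilcoxon_rank_sum(amp.iloc[groups == "case", j],
                              amp.iloc[groups == "control", j])[1]
            for j in range(amp.shape[1])
        ])
        frac = (ps < 0.05).mean()
        assert 0.03 <= frac <= 0.07


class TestBH:
    def test_worked_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged_and_all_ones(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_reference_stepup_and_invariants(self, ps):
        adj = bh_adjust(ps)
        assert adj == pytest.approx(bh_stepup(ps), abs=1e-12)
        assert (adj >= np.asarray(ps) - 1e-15).all()
        assert ((0 <= adj) & (adj <= 1)).all()
        # monotone in the order statistics
        order = np.argsort(ps, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestFoldChange:
    @pytest.mark.parametrize(
        "case,control,expected",
        [
            ([2.0, 2.0], [2.0, 2.0], 1.0),
            ([4.0, 4.0], [1.0, 1.0], 4.0),
            ([1.0, 1.0], [4.0, 4.0], -4.0),
        ],
    )
    def test_signed_convention(self, case, control, expected):
        assert fold_change(case, control) == pytest.approx(expected)

    def test_zero_sentinels(self):
        assert fold_change([1.0], [0.0]) == np.inf
        assert np.isnan(fold_change([0.0], [0.0]))

    def test_zeros_enter_the_means(self):
        # mean(case) = 2, mean(control) = 1 -> +2
        assert fold_change([4.0, 0.0], [2.0, 0.0]) == pytest.approx(2.0)


class TestDiscoverPanel:
    def test_small_group_refused_with_power_warning(self):
        m, groups = _matrix_from_detection([True, True], [True] * 6)
        with pytest.raises(PowerError, match="power"):
            discover_panel(m, groups)

    def test_recovers_markers_with_low_false_fraction(self, study):
        """22 vs 22 discovery design: >= 80% of the 20 markers found,
        false discoveries <= 10% of the panel."""
        assert study.marker_recovery >= 0.8
        assert study.panel_false_fraction <= 0.10

    def test_null_cohorts_rarely_produce_panels(self):
        """Under the global null BH keeps the panel empty in >= 90% of seeds."""
        empty = 0
        n_seeds = 40
        for seed in range(n_seeds):
            sim = simulate_cohort_full(
                SimConfig(n_case=12, n_control=12, n_peptides=120, n_markers=0,
                          n_housekeeping=20, seed=3000 + seed)
            )
            matrix = AmplitudeMatrix(
                sim.base_amplitudes,
                pd.Series([p.group for p in sim.profiles], index=sim.base_amplitudes.index),
            )
            entries = discover_panel(matrix)
            empty += not entries
        assert empty >= 0.9 * n_seeds

    def test_invariant_to_sample_and_peptide_order(self):
        sim = simulate_cohort_full(
            SimConfig(n_case=8, n_control=8, n_peptides=60, n_markers=8,
                      n_housekeeping=12, seed=66)
        )
        groups = pd.Series([p.group for p in sim.profiles], index=sim.base_amplitudes.index)
        m1 = AmplitudeMatrix(sim.base_amplitudes, groups)
        rng = np.random.default_rng(1)
        rows = rng.permutation(m1.sample_ids)
        cols = rng.permutation(m1.peptide_ids)
        m2 = AmplitudeMatrix(sim.base_amplitudes.loc[rows, cols], groups)
        e1 = discover_panel(m1)
        e2 = discover_panel(m2)
        assert [(e.peptide_id, e.p_adj) for e in e1] == [(e.peptide_id, e.p_adj) for e in e2]

    def test_entries_sorted_and_p_ordering(self, study):
        entries = study.results.entries
        keys = [(e.p_adj, e.peptide_id) for e in entries]
        assert keys == sorted(keys)
        for e in entries:
            assert 0 <= e.p_raw <= e.p_adj <= 1
            assert (e.fold_change > 0) == (e.direction == "up")
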