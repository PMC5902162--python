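"""Windowed ROC discrimination, BH selection, exclusion and first-spike
reduction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from firstspike import (
    PopulationSpec,
    UnitRecording,
    bh_select,
    count_in_window,
    discrimination_curve,
    exclusion_filter,
    first_spike_reduce,
    generate_population,
    unit_auc,
)
from firstspike.errors import ValidationError

from .test_behavior import brute_force_auc


def exact_poisson_auc(lam_hi, lam_lo, k_max=200):
    """Truncated double-sum oracle: P(X > Y) + 0.5 P(X = Y)."""
    p_hi = stats.poisson.pmf(np.arange(k_max), lam_hi)
    p_lo = stats.poisson.pmf(np.arange(k_max), lam_lo)
    gt = np.tril(np.ones((k_max, k_max)), -1)
    return float(p_hi @ gt @ p_lo + 0.5 * p_hi @ p_lo)


class TestCountInWindow:
    def test_empty_trains_all_zero(self):
        unit = UnitRecording("u", {0: [], 1: []})
        assert count_in_window(unit, 40.0, 80.0).tolist() == [0, 0]

    def test_half_open_right_edge_excluded(self):
        unit = UnitRecording("u", {0: [0.120]})
        assert count_in_window(unit, 40.0, 80.0).tolist() == [0]
        assert count_in_window(unit, 40.0, 80.001).tolist() == [1]

    def test_hand_check(self):
        unit = UnitRecording("u", {0: [0.05, 0.10, 0.25]})
        # window [0.04, 0.12): spikes at 0.05 and 0.10
        assert count_in_window(unit, 40.0, 80.0).tolist() == [2]

    def test_left_edge_included(self):
        unit = UnitRecording("u", {0: [0.040]})
        assert count_in_window(unit, 40.0, 80.0).tolist() == [1]


class TestUnitAuc:
    def test_identical_distributions(self):
        auc, _ = unit_auc([0, 1, 2], [0, 1, 2])
        assert auc == pytest.approx(0.5)

    def test_brute_force_cross_pairs(self):
        auc, _ = unit_auc([2, 2], [0, 1])
        assert auc == 1.0

    @given(
        x=st.lists(st.integers(0, 4), min_size=1, max_size=8),
        y=st.lists(st.integers(0, 4), min_size=1, max_size=8),
    )
    @settings(max_examples=300, deadline=None)
    def test_oracle_equivalence_small_samples(self, x, y):
        auc, _ = unit_auc(x, y)
        assert auc == pytest.approx(brute_force_auc(x, y))

    def test_converges_to_analytic_poisson_value(self):
        """Large samples from Poisson(0.6)/Poisson(0.22) approach the
        truncated-double-sum value ~0.634."""
        rng = np.random.default_rng(5)
        auc, p = unit_auc(rng.poisson(0.6, 50_000), rng.poisson(0.22, 50_000))
        assert auc == pytest.approx(exact_poisson_auc(0.6, 0.22), abs=0.01)
        assert p < 1e-10


class TestBhSelect:
    def test_all_ones_none_selected(self):
        flags, cutoff = bh_select([1.0, 1.0, 1.0], 0.05)
        assert not flags.any() and np.isnan(cutoff)

    def test_all_zero_selected(self):
        flags, cutoff = bh_select([0.0, 0.0], 0.05)
        assert flags.all() and cutoff == 0.0

    def test_step_up_hand_case(self):
        # thresholds 0.0125/0.025/0.0375/0.05 -> largest passing is p=0.04
        flags, cutoff = bh_select([0.001, 0.01, 0.02, 0.04], 0.05)
        assert flags.all() and cutoff == pytest.approx(0.04)

    @given(
        pvals=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12),
        fdr=st.sampled_from([0.01, 0.05, 0.1, 0.25]),
    )
    @settings(max_examples=400, deadline=None)
    def test_agrees_with_exhaustive_definition(self, pvals, fdr):
        """Every flag pattern matches a direct scan of the step-up rule."""
        flags, cutoff = bh_select(pvals, fdr)
        p = np.array(pvals)
        m = len(p)
        srt = np.sort(p)
        passing = [i for i in range(m) if srt[i] <= (i + 1) / m * fdr]
        if not passing:
            assert not flags.any()
        else:
            expected = p <= srt[max(passing)]
            assert flags.tolist() == expected.tolist()
            assert cutoff == pytest.approx(srt[max(passing)])

    @given(pvals=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_statsmodels(self, pvals):
        flags, _ = bh_select(pvals, 0.05)
        reference = multipletests(pvals, alpha=0.05, method="fdr_bh")[0]
        assert flags.tolist() == reference.tolist()


class TestExclusionFilter:
    def test_silent_unit_excluded(self):
        silent = UnitRecording("s", {i: [] for i in range(10)})
        _, excluded = exclusion_filter([silent], onset_ms=40.0)
        assert excluded == ["s"]

    def test_one_spike_per_trial_retained(self):
        busy = UnitRecording("b", {i: [0.1] for i in range(10)})
        retained, _ = exclusion_filter([busy], onset_ms=40.0)
        assert [u.unit_id for u in retained] == ["b"]

    def test_rate_arithmetic(self):
        # 10 spikes over 90 trials -> mean 0.111 < 1/6 -> excluded
        spikes = {i: ([0.1] if i < 10 else []) for i in range(90)}
        _, excluded = exclusion_filter([UnitRecording("m", spikes)], onset_ms=40.0)
        assert excluded == ["m"]

    def test_boundary_is_retained(self):
        # exactly 1 spike every 6 trials is NOT strictly below the threshold
        spikes = {i: ([0.1] if i % 6 == 0 else []) for i in range(12)}
        retained, _ = exclusion_filter([UnitRecording("e", spikes)], onset_ms=40.0)
        assert len(retained) == 1


class TestFirstSpikeReduce:
    def test_keeps_first_post_onset_spike(self):
        unit = UnitRecording("u", {0: [0.01, 0.05, 0.09]})
        reduced = first_spike_reduce(unit, 40.0)
        assert reduced.spikes[0].tolist() == [0.05]

    def test_empty_trial_stays_empty(self):
        reduced = first_spike_reduce(UnitRecording("u", {0: []}), 40.0)
        assert reduced.spikes[0].size == 0

    def test_idempotent(self, simple_unit):
        once = first_spike_reduce(simple_unit, 40.0)
        twice = first_spike_reduce(once, 40.0)
        for t in once.spikes:
            assert np.array_equal(once.spikes[t], twice.spikes[t])

    def test_counts_never_exceed_one(self, default_population):
        pop = default_population
        for unit in pop.units[:5]:
            reduced = first_spike_reduce(unit, pop.onset_ms)
            assert count_in_window(reduced, pop.onset_ms, 300.0).max() <= 1


class TestDiscriminationCurve:
    def test_fraction_at_300ms_is_one(self, default_population):
        pop = default_population
        res = discrimination_curve(pop.units, pop.trials, pop.onset_ms)
        frac_300 = res.fractions.loc[
            res.fractions["interval_ms"] == 300.0, "fraction_discriminating"
        ].item()
        if res.n_discriminating:
            assert frac_300 == 1.0

    def test_silent_population_has_no_discriminators(self, small_trials):
        silent = [UnitRecording(f"s{i}", {t: [] for t in range(6)}) for i in range(4)]
        res = discrimination_curve(silent, small_trials, 40.0)
        assert res.n_discriminating == 0

    def test_power_on_designed_discriminators(self):
        """At the generator's condition (0.6 vs 0.22 spikes, 100 trials per
        stimulus) at least 90% of discriminating-by-design units are flagged
        at 300 ms."""
        pop = generate_population(
            PopulationSpec(n_units=40, n_trials_per_stimulus=100), seed=2
        )
        res = discrimination_curve(pop.units, pop.trials, pop.onset_ms)
        designed = set(
            pop.unit_truth.loc[pop.unit_truth.discriminating_by_design, "unit_id"]
        )
        flagged = designed & set(res.discriminating)
        assert len(flagged) / len(designed) >= 0.9

    def test_preference_matches_mean_count_sign(self, default_population):
        pop = default_population
        res = discrimination_curve(pop.units, pop.trials, pop.onset_ms)
        at_300 = res.table[res.table["interval_ms"] == 300.0].set_index("unit_id")
        for unit_id, row in at_300.iterrows():
            expected = (
                "target"
                if row["mean_count_target"] >= row["mean_count_distractor"]
                else "distractor"
            )
            assert res.preferences[unit_id] == expected

    def test_grid_must_contain_defining_window(self, default_population):
        pop = default_population
        with pytest.raises(ValidationError):
            discrimination_curve(pop.units, pop.trials, pop.onset_ms, interval_grid=[20, 80])
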