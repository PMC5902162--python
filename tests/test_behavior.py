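"""Behavioral readouts: stop classification, accuracy, ROC, CIs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from firstspike import (
    accuracy,
    behavior_summary,
    binomial_ci95,
    choice_ranksum,
    classify_stops,
    ideal_observer_auc,
)
from firstspike.errors import ValidationError


def brute_force_auc(x, y):
    """Independent oracle: exhaustive cross-pair enumeration."""
    wins = sum(1.0 for a in x for b in y if a > b)
    ties = sum(1.0 for a in x for b in y if a == b)
    return (wins + 0.5 * ties) / (len(x) * len(y))


class TestClassifyStops:
    def test_boundary_counts_as_stop(self, small_trials):
        out = classify_stops(small_trials.assign(hold_time=[0.9, 0.1, 0.9, 0.3, 0.2, 1.1]), 0.9)
        assert bool(out.loc[0, "stop"]) and bool(out.loc[2, "stop"])

    def test_hand_enumeration(self):
        trials = pd.DataFrame(
            {
                "trial_id": [0, 1, 2],
                "stimulus": ["target"] * 3,
                "hold_time": [0.2, 0.7, 1.1],
                "led": ["off"] * 3,
            }
        )
        assert classify_stops(trials, 0.9)["stop"].tolist() == [False, False, True]

    def test_zero_hold_is_non_stop(self, small_trials):
        out = classify_stops(small_trials.assign(hold_time=0.0), 0.9)
        assert not out["stop"].any()

    def test_nonpositive_threshold_rejected(self, small_trials):
        with pytest.raises(ValidationError):
            classify_stops(small_trials, 0.0)


class TestAccuracy:
    def test_perfect_discrimination(self, small_trials):
        t = small_trials.assign(
            stop=small_trials["stimulus"] == "target"
        )
        assert accuracy(t) == 100.0

    def test_direct_evaluation(self):
        # 8/10 targets stopped, 6/10 distractors non-stop -> 70%
        trials = pd.DataFrame(
            {
                "trial_id": range(20),
                "stimulus": ["target"] * 10 + ["distractor"] * 10,
                "hold_time": [1.0] * 20,
                "led": ["off"] * 20,
                "stop": [True] * 8 + [False] * 2 + [True] * 4 + [False] * 6,
            }
        )
        assert accuracy(trials) == pytest.approx(70.0)

    def test_missing_class_named(self):
        trials = pd.DataFrame(
            {
                "trial_id": [0],
                "stimulus": ["target"],
                "hold_time": [1.0],
                "led": ["off"],
                "stop": [True],
            }
        )
        with pytest.raises(ValidationError, match="distractor"):
            accuracy(trials)

    @given(q=st.floats(0.05, 0.95), seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_stimulus_blind_observer_is_at_chance(self, q, seed):
        """Stopping independent of stimulus averages to 50% for any stop rate."""
        rng = np.random.default_rng(seed)
        n = 4000
        trials = pd.DataFrame(
            {
                "trial_id": range(n),
                "stimulus": rng.choice(["target", "distractor"], n),
                "hold_time": [1.0] * n,
                "led": ["off"] * n,
                "stop": rng.uniform(size=n) < q,
            }
        )
        se = 100 * np.sqrt(q * (1 - q)) * np.sqrt(1 / (trials.stimulus == "target").sum()
                                                  + 1 / (trials.stimulus == "distractor").sum()) / 2
        assert abs(accuracy(trials) - 50.0) < 4 * se + 1e-9


class TestIdealObserverAuc:
    def test_identical_samples_half(self):
        assert ideal_observer_auc([1, 2, 3], [1, 2, 3]) == pytest.approx(0.5)

    def test_full_separation(self):
        assert ideal_observer_auc([5, 6], [1, 2]) == 1.0

    def test_hand_cross_pairs(self):
        # pairs of T=[1,2] vs D=[1,3]: one win (2>1), one tie (1=1) -> 0.375
        assert ideal_observer_auc([1, 2], [1, 3]) == pytest.approx(0.375)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            ideal_observer_auc([], [1.0])

    @given(
        x=st.lists(st.integers(0, 5), min_size=1, max_size=8),
        y=st.lists(st.integers(0, 5), min_size=1, max_size=8),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_oracle(self, x, y):
        assert ideal_observer_auc(x, y) == pytest.approx(brute_force_auc(x, y))

    @given(
        x=st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=8),
        y=st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=8),
    )
    @settings(max_examples=200, deadline=None)
    def test_complementarity(self, x, y):
        assert ideal_observer_auc(x, y) + ideal_observer_auc(y, x) == pytest.approx(1.0)


class TestChoiceRanksum:
    def test_identical_samples(self):
        assert choice_ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) > 0.99

    def test_exact_permutation_small_samples(self):
        # most extreme labeling of C(6,3)=20 -> two-sided p = 2/20
        assert choice_ranksum([5, 6, 7], [1, 2, 3]) == pytest.approx(0.1)

    def test_large_separation_is_significant(self):
        rng = np.random.default_rng(0)
        assert choice_ranksum(rng.normal(10, 1, 300), rng.normal(0, 1, 300)) < 1e-6


class TestBinomialCi95:
    def test_boundary_cases(self):
        assert binomial_ci95(10, 10)[1] == pytest.approx(1.0)
        assert binomial_ci95(0, 10)[0] == pytest.approx(0.0)

    def test_clopper_pearson_values(self):
        lo, hi = binomial_ci95(5, 10)
        assert lo == pytest.approx(0.187, abs=5e-4)
        assert hi == pytest.approx(0.813, abs=5e-4)

    def test_contains_point_estimate(self):
        lo, hi = binomial_ci95(3, 17)
        assert lo < 3 / 17 < hi

    def test_zero_n_rejected(self):
        with pytest.raises(ValidationError):
            binomial_ci95(0, 0)


def test_behavior_summary_fields(small_trials):
    s = behavior_summary(small_trials, 0.9)
    assert s.n_target == 3 and s.n_distractor == 3
    assert 0 <= s.ideal_observer_auc <= 1
    assert 0 <= s.accuracy_percent <= 100
    assert s.stop_prob_target_ci[0] <= s.stop_prob_target <= s.stop_prob_target_ci[1]
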