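"""Statistical contracts of the synthetic-data generators."""

import numpy as np
import pytest

from firstspike import (
    BehaviorSpec,
    LfpSpec,
    PopulationSpec,
    accuracy,
    count_in_window,
    generate_behavior,
    generate_lfp,
    generate_passive,
    generate_population,
)
from firstspike.errors import ValidationError
from firstspike.spike_stats import poisson_fit


class TestGeneratePopulation:
    def test_zero_rates_give_empty_trains(self):
        spec = PopulationSpec(
            n_units=3,
            n_trials_per_stimulus=5,
            preferred_mean_80ms=0.0,
            nonpreferred_mean_80ms=0.0,
            baseline_rate_hz=0.0,
        )
        pop = generate_population(spec, 0)
        assert all(s.size == 0 for u in pop.units for s in u.spikes.values())

    def test_same_seed_identical(self):
        spec = PopulationSpec(n_units=4, n_trials_per_stimulus=10)
        a = generate_population(spec, 5)
        b = generate_population(spec, 5)
        assert a.onset_ms == b.onset_ms
        for ua, ub in zip(a.units, b.units):
            for t in ua.spikes:
                assert np.array_equal(ua.spikes[t], ub.spikes[t])

    def test_poisson_mean_within_three_se(self):
        """Empirical mean response count matches the spec'd 0.6 within
        3 sqrt(lam/n) at 200 trials per stimulus."""
        spec = PopulationSpec(n_units=1, n_trials_per_stimulus=200, fraction_preferring_target=1.0)
        pop = generate_population(spec, 9)
        target_ids = pop.trials.loc[pop.trials.stimulus == "target", "trial_id"].tolist()
        counts = count_in_window(pop.units[0], pop.onset_ms, 80.0, target_ids)
        se = np.sqrt(0.6 / 200)
        assert abs(counts.mean() - 0.6) < 3 * se

    def test_counts_pass_poisson_goodness_of_fit(self):
        spec = PopulationSpec(n_units=1, n_trials_per_stimulus=150, fraction_preferring_target=1.0)
        pop = generate_population(spec, 21)
        target_ids = pop.trials.loc[pop.trials.stimulus == "target", "trial_id"].tolist()
        counts = count_in_window(pop.units[0], pop.onset_ms, 80.0, target_ids)
        assert poisson_fit(counts).r2 >= 0.9

    def test_nondiscriminating_units_have_equal_means(self):
        spec = PopulationSpec(
            n_units=1, n_trials_per_stimulus=600, fraction_nondiscriminating=1.0
        )
        pop = generate_population(spec, 13)
        t_ids = pop.trials.loc[pop.trials.stimulus == "target", "trial_id"].tolist()
        d_ids = pop.trials.loc[pop.trials.stimulus == "distractor", "trial_id"].tolist()
        mean_t = count_in_window(pop.units[0], pop.onset_ms, 80.0, t_ids).mean()
        mean_d = count_in_window(pop.units[0], pop.onset_ms, 80.0, d_ids).mean()
        mid = (0.6 + 0.22) / 2
        assert abs(mean_t - mean_d) < 6 * np.sqrt(mid / 600)

    def test_led_truncation_removes_late_spikes(self):
        spec = PopulationSpec(n_units=3, n_trials_per_stimulus=20, led_truncation_ms=40.0)
        pop = generate_population(spec, 4)
        cut_s = (pop.onset_ms + 40.0 + 8.0) / 1000.0  # LED onset + silencing delay
        assert (pop.trials["led"] == "on").all()
        for unit in pop.units:
            for spk in unit.spikes.values():
                assert (spk < cut_s).all()

    def test_zero_trials_rejected(self):
        with pytest.raises(ValidationError):
            generate_population(PopulationSpec(n_trials_per_stimulus=0), 0)


class TestGenerateBehavior:
    def test_deterministic_observer_is_perfect(self):
        spec = BehaviorSpec(n_trials=400, stop_prob_target=1.0, stop_prob_distractor=0.0)
        trials = generate_behavior(spec, 0)
        assert accuracy(trials) > 99.0

    def test_stimulus_blind_observer_near_chance(self):
        """Equal hold-time distributions: accuracy tends to 50% as n grows."""
        spec = BehaviorSpec(n_trials=10_000, p_target=0.5, stop_prob_target=0.3,
                            stop_prob_distractor=0.3)
        trials = generate_behavior(spec, 1)
        se = 100 * np.sqrt(0.3 * 0.7) * np.sqrt(2 / 5000) / 2
        assert abs(accuracy(trials) - 50.0) < 3 * se

    def test_target_fraction_within_binomial_se(self):
        trials = generate_behavior(BehaviorSpec(n_trials=10_000, p_target=0.25), 2)
        frac = (trials["stimulus"] == "target").mean()
        assert abs(frac - 0.25) < 3 * np.sqrt(0.25 * 0.75 / 10_000)

    def test_stop_flag_recomputable(self):
        spec = BehaviorSpec(n_trials=500)
        trials = generate_behavior(spec, 3)
        assert (trials["stop"] == (trials["hold_time"] >= spec.hold_threshold)).all()


class TestGenerateLfp:
    def test_zero_amplitude_has_no_ground_truth(self):
        block = generate_lfp(LfpSpec(deflection_amplitude=0.0), 0)
        assert block.ground_truth_onset_ms is None

    def test_same_seed_identical(self):
        a = generate_lfp(LfpSpec(), 7)
        b = generate_lfp(LfpSpec(), 7)
        assert np.array_equal(a.traces, b.traces)

    def test_span_and_channels(self):
        spec = LfpSpec(n_channels=3, span_ms=(-100.0, 400.0))
        block = generate_lfp(spec, 1)
        assert block.n_channels == 3
        assert block.times[0] * 1000 == pytest.approx(-100.0)
        assert block.times[-1] * 1000 == pytest.approx(400.0, abs=1.0)

    def test_invalid_span_rejected(self):
        with pytest.raises(ValidationError):
            generate_lfp(LfpSpec(span_ms=(-50.0, 400.0)), 0)


class TestGeneratePassive:
    def test_flat_tuning_limit(self):
        """kappa -> 0 flattens the curve: OSI near zero."""
        from firstspike import osi, tuning_curve

        spec = PopulationSpec(n_units=1, tuning_kappa=1e-9, passive_n_reps=60)
        responses, _ = generate_passive(spec, 0)
        assert osi(tuning_curve(responses)) < 0.1

    def test_counts_are_deterministic_per_seed(self):
        spec = PopulationSpec(n_units=2)
        a, _ = generate_passive(spec, 11)
        b, _ = generate_passive(spec, 11)
        assert a.equals(b)

    def test_row_count(self):
        spec = PopulationSpec(n_units=3, passive_n_orientations=12, passive_n_reps=5)
        responses, truth = generate_passive(spec, 0)
        assert len(responses) == 3 * 12 * 5
        assert len(truth) == 3
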