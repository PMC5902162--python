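"""Synthetic sessions with the statistical structure the analyses assume.

The generator emulates a head-fixed visual discrimination session: Poisson
spike counts in an 80 ms response window with stimulus-dependent means (0.6
spikes for the preferred stimulus vs 0.22 for the non-preferred one, the
medians reported for discriminating units in mouse V1), a cortical response
onset ~40 ms after stimulus onset with 5 ms across-session spread, a 12 ms
preferred/non-preferred first-spike latency shift, lognormal hold times whose
exceedance of the reward threshold defines stop trials, circular-Gaussian
orientation tuning for passive viewing, and a band-limited noisy LFP with a
smooth evoked deflection.

All generators are pure functions of (spec, seed).  Response spikes occupy
``[onset, onset + 80 ms)``; baseline spikes are homogeneous Poisson *before*
the cortical onset only, so post-onset first-spike statistics are governed by
the response latency density alone.  The latency density is a gamma truncated
to the response window whose scale is re-solved numerically so the truncated
mean lands exactly on the nominal value — naive truncation would shrink the
12 ms shift the analyses are meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .datatypes import LfpBlock, UnitRecording, validate_trial_table
from .errors import ValidationError

__all__ = [
    "PopulationSpec",
    "BehaviorSpec",
    "LfpSpec",
    "SyntheticPopulation",
    "generate_population",
    "generate_behavior",
    "generate_lfp",
    "generate_passive",
]

RESPONSE_WINDOW_MS = 80.0
TRIAL_SPAN_S = (-0.2, 0.35)  # recorded span around stimulus onset
SILENCING_DELAY_MS = 8.0  # optogenetic silencing lag after LED onset


@dataclass
class PopulationSpec:
    """Conditions for one synthetic recording session."""

    n_units: int = 72
    n_trials_per_stimulus: int = 100
    preferred_mean_80ms: float = 0.6  # spikes per 80 ms, preferred stimulus
    nonpreferred_mean_80ms: float = 0.22
    onset_latency_ms: float = 40.0  # cortical onset after stimulus onset
    onset_latency_sd_ms: float = 5.0  # across-session spread
    first_spike_latency_shift_ms: float = 12.0  # non-preferred lags preferred
    preferred_latency_mean_ms: float = 34.0  # mean response latency, preferred
    latency_gamma_shape: float = 3.0
    baseline_rate_hz: float = 1.0  # pre-onset spontaneous rate
    fraction_preferring_target: float = 0.5
    fraction_nondiscriminating: float = 0.0
    led_truncation_ms: float | None = None  # LED onset after cortical onset
    # passive-viewing parameters
    passive_n_orientations: int = 12  # 15 degree steps over [0, 180)
    passive_n_reps: int = 30
    passive_peak_rate_hz: float = 10.0
    passive_baseline_rate_hz: float = 0.5
    tuning_kappa: float = 1.0  # circular-Gaussian concentration (2θ space)
    passive_window_ms: float = 330.0
    # behavioral columns of the emitted trial table
    hold_threshold_s: float = 0.9
    stop_prob_target: float = 0.9
    stop_prob_distractor: float = 0.1
    hold_sigma: float = 0.5  # lognormal shape of hold times

    def validate(self) -> None:
        if self.n_units < 1:
            raise ValidationError("n_units must be >= 1")
        if self.n_trials_per_stimulus < 1:
            raise ValidationError("n_trials_per_stimulus must be >= 1")
        if min(self.preferred_mean_80ms, self.nonpreferred_mean_80ms) < 0:
            raise ValidationError("spike-count means must be non-negative")
        for name in ("fraction_preferring_target", "fraction_nondiscriminating"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if not 0 < self.preferred_latency_mean_ms < RESPONSE_WINDOW_MS:
            raise ValidationError("preferred latency mean must fall inside the response window")
        if not (
            0
            < self.preferred_latency_mean_ms + self.first_spike_latency_shift_ms
            < RESPONSE_WINDOW_MS
        ):
            raise ValidationError("non-preferred latency mean must fall inside the response window")


@dataclass
class BehaviorSpec:
    """Conditions for a purely behavioral synthetic session."""

    n_trials: int = 200
    p_target: float = 0.4
    stop_prob_target: float = 0.9
    stop_prob_distractor: float = 0.1
    hold_threshold: float = 0.9  # s
    hold_sigma: float = 0.5
    # optional explicit lognormal (mu, sigma) of hold time per stimulus;
    # overrides the stop-probability calibration when given
    hold_time_distributions: dict | None = None

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ValidationError("n_trials must be >= 1")
        for name in ("p_target", "stop_prob_target", "stop_prob_distractor"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.hold_threshold <= 0:
            raise ValidationError("hold_threshold must be positive")


@dataclass
class LfpSpec:
    """Conditions for a synthetic trial-averaged LFP block."""

    n_channels: int = 4
    fs: float = 2000.0  # Hz
    noise_sd: float = 5e-6  # volts, post-averaging
    noise_bandwidth_hz: float = 100.0  # trial-averaged LFP noise is smooth
    deflection_amplitude: float = 10.0  # multiples of noise_sd
    deflection_onset_ms: float = 40.0
    deflection_tau_ms: float = 15.0  # rise time constant of the alpha shape
    span_ms: tuple[float, float] = (-100.0, 400.0)

    def validate(self) -> None:
        if self.fs <= 0 or self.n_channels < 1:
            raise ValidationError("fs and n_channels must be positive")
        lo, hi = self.span_ms
        if lo > -80.0 or hi < 300.0:
            raise ValidationError("trace span must cover at least [-80, +300] ms")
        if not lo < self.deflection_onset_ms < hi:
            raise ValidationError("deflection onset must lie inside the trace span")


# --------------------------------------------------------------------------
# latency density: gamma truncated to the response window, truncated-mean
# matched to the nominal latency


def _truncated_gamma_scale(shape: float, target_mean_ms: float, upper_ms: float) -> float:
    """Scale for which the gamma truncated to [0, upper] has the target mean."""
    sup = upper_ms * shape / (shape + 1.0)  # scale -> inf limit of the truncated mean
    if not 0 < target_mean_ms < sup:
        raise ValidationError(
            f"target latency mean {target_mean_ms} ms unreachable below {sup:.1f} ms"
        )

    def trunc_mean(scale: float) -> float:
        a = upper_ms / scale
        return shape * scale * special.gammainc(shape + 1.0, a) / special.gammainc(shape, a)

    return float(optimize.brentq(lambda s: trunc_mean(s) - target_mean_ms, 1e-6, 1e5))


def _first_spike_mean_ms(
    shape: float, scale: float, upper_ms: float, lam: float, n_grid: int = 4000
) -> float:
    """Mean time of the *first* response spike, conditional on at least one.

    With the spike count Poisson(lam) and spike times iid from the truncated
    gamma, the conditional survival of the minimum is
    ``(exp(-lam F(t)) - exp(-lam)) / (1 - exp(-lam))`` and the mean is its
    integral over the response window.
    """
    t = np.linspace(0.0, upper_ms, n_grid)
    cdf = special.gammainc(shape, t / scale) / special.gammainc(shape, upper_ms / scale)
    surv = (np.exp(-lam * cdf) - np.exp(-lam)) / -np.expm1(-lam)
    return float(np.trapezoid(surv, t))


def _first_spike_calibrated_scale(
    shape: float, target_mean_ms: float, upper_ms: float, lam: float
) -> float:
    """Scale for which the mean first-spike time equals ``target_mean_ms``.

    For lam -> 0 this reduces to matching the truncated per-spike mean; for
    larger lam the minimum statistic pulls the first spike earlier, so the
    per-spike density is shifted later to compensate.
    """
    if lam <= 0:
        return _truncated_gamma_scale(shape, target_mean_ms, upper_ms)
    return float(
        optimize.brentq(
            lambda s: _first_spike_mean_ms(shape, s, upper_ms, lam) - target_mean_ms,
            1e-6,
            1e5,
        )
    )


def _sample_truncated_gamma(
    rng: np.random.Generator, n: int, shape: float, scale: float, upper_ms: float
) -> np.ndarray:
    """Inverse-CDF sampling of a gamma conditioned on being below ``upper_ms``."""
    mass = special.gammainc(shape, upper_ms / scale)
    u = rng.uniform(0.0, mass, size=n)
    return scale * special.gammaincinv(shape, u)


def _calibrated_lognormal_mu(stop_prob: float, threshold: float, sigma: float) -> float:
    """Lognormal location with P(hold >= threshold) = stop_prob."""
    q = min(max(stop_prob, 1e-9), 1 - 1e-9)
    return float(np.log(threshold) - sigma * stats.norm.ppf(1.0 - q))


def _make_trials(
    rng: np.random.Generator,
    n_target: int,
    n_distractor: int,
    stop_prob_target: float,
    stop_prob_distractor: float,
    hold_threshold: float,
    hold_sigma: float,
    led_onset_ms: float | None,
) -> pd.DataFrame:
    stimulus = np.array(["target"] * n_target + ["distractor"] * n_distractor)
    rng.shuffle(stimulus)
    mu_t = _calibrated_lognormal_mu(stop_prob_target, hold_threshold, hold_sigma)
    mu_d = _calibrated_lognormal_mu(stop_prob_distractor, hold_threshold, hold_sigma)
    mu = np.where(stimulus == "target", mu_t, mu_d)
    hold = np.exp(rng.normal(mu, hold_sigma))
    trials = pd.DataFrame(
        {
            "trial_id": np.arange(stimulus.size),
            "stimulus": stimulus,
            "orientation": np.where(stimulus == "target", 90.0, 45.0),
            "hold_time": hold,
            "led": "on" if led_onset_ms is not None else "off",
            "led_onset_ms": led_onset_ms if led_onset_ms is not None else np.nan,
            "stop": hold >= hold_threshold,
        }
    )
    return validate_trial_table(trials)


@dataclass
class SyntheticPopulation:
    """Output bundle of :func:`generate_population`."""

    units: list[UnitRecording]
    trials: pd.DataFrame
    onset_ms: float  # ground-truth cortical onset of this session
    unit_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    spec: PopulationSpec | None = None


def generate_population(spec: PopulationSpec, seed: int) -> SyntheticPopulation:
    """One synthetic session: trial table plus per-unit spike trains.

    Per unit and stimulus, spike counts in the 80 ms response window are
    Poisson with the spec'd mean; response spike times follow the
    truncated-gamma latency density whose mean differs by the spec'd shift
    between preferred and non-preferred stimulus.  Non-discriminating units
    get the average mean for both stimuli.  When ``led_truncation_ms`` is
    set, every spike after LED onset + 8 ms silencing delay is removed.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    onset_ms = float(rng.normal(spec.onset_latency_ms, spec.onset_latency_sd_ms))
    onset_ms = max(onset_ms, 1.0)
    onset_s = onset_ms / 1000.0

    trials = _make_trials(
        rng,
        spec.n_trials_per_stimulus,
        spec.n_trials_per_stimulus,
        spec.stop_prob_target,
        spec.stop_prob_distractor,
        spec.hold_threshold_s,
        spec.hold_sigma,
        spec.led_truncation_ms,
    )

    shape = spec.latency_gamma_shape
    mean_pref_lat = spec.preferred_latency_mean_ms
    mean_nonpref_lat = mean_pref_lat + spec.first_spike_latency_shift_ms
    mean_mid_lat = 0.5 * (mean_pref_lat + mean_nonpref_lat)
    # latency-density scale per (first-spike mean, count mean) combination
    scales: dict[tuple[float, float], float] = {}

    def _scale_for(lat_mean: float, count_mean: float) -> float:
        key = (lat_mean, count_mean)
        if key not in scales:
            scales[key] = _first_spike_calibrated_scale(
                shape, lat_mean, RESPONSE_WINDOW_MS, count_mean
            )
        return scales[key]

    n_nondisc = int(round(spec.fraction_nondiscriminating * spec.n_units))
    n_target_pref = int(round(spec.fraction_preferring_target * (spec.n_units - n_nondisc)))
    roles = (
        ["nondiscriminating"] * n_nondisc
        + ["target"] * n_target_pref
        + ["distractor"] * (spec.n_units - n_nondisc - n_target_pref)
    )
    rng.shuffle(roles)

    cut_s = None
    if spec.led_truncation_ms is not None:
        cut_s = onset_s + (spec.led_truncation_ms + SILENCING_DELAY_MS) / 1000.0

    t_pre, _ = TRIAL_SPAN_S
    baseline_span = onset_s - t_pre
    stim_by_trial = trials.set_index("trial_id")["stimulus"]

    units, truth_rows = [], []
    for i, role in enumerate(roles):
        mid = 0.5 * (spec.preferred_mean_80ms + spec.nonpreferred_mean_80ms)
        if role == "nondiscriminating":
            means = {"target": mid, "distractor": mid}
            lat_means = {"target": mean_mid_lat, "distractor": mean_mid_lat}
        elif role == "target":
            means = {"target": spec.preferred_mean_80ms, "distractor": spec.nonpreferred_mean_80ms}
            lat_means = {"target": mean_pref_lat, "distractor": mean_nonpref_lat}
        else:
            means = {"target": spec.nonpreferred_mean_80ms, "distractor": spec.preferred_mean_80ms}
            lat_means = {"target": mean_nonpref_lat, "distractor": mean_pref_lat}

        spikes = {}
        for trial_id, stim in stim_by_trial.items():
            n_base = rng.poisson(spec.baseline_rate_hz * baseline_span)
            base = rng.uniform(t_pre, onset_s, size=n_base)
            n_resp = rng.poisson(means[stim])
            lat = _sample_truncated_gamma(
                rng, n_resp, shape, _scale_for(lat_means[stim], means[stim]), RESPONSE_WINDOW_MS
            )
            times = np.sort(np.concatenate([base, onset_s + lat / 1000.0]))
            if cut_s is not None:
                times = times[times < cut_s]
            spikes[int(trial_id)] = times
        units.append(UnitRecording(unit_id=f"u{i:03d}", spikes=spikes))
        truth_rows.append(
            {
                "unit_id": f"u{i:03d}",
                "role": role,
                "discriminating_by_design": role != "nondiscriminating",
                "preferred_stimulus": role if role in ("target", "distractor") else "none",
            }
        )
    return SyntheticPopulation(
        units=units,
        trials=trials,
        onset_ms=onset_ms,
        unit_truth=pd.DataFrame(truth_rows),
        spec=spec,
    )


def generate_behavior(spec: BehaviorSpec, seed: int) -> pd.DataFrame:
    """Trial table for a behavior-only session.

    Stimulus identity is Bernoulli(p_target); hold times are lognormal with a
    per-stimulus location calibrated so that P(hold >= threshold) equals the
    spec'd stop probability (or drawn from explicit distributions when
    given); the stop flag is re-derivable from hold time and threshold.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    stimulus = np.where(rng.uniform(size=spec.n_trials) < spec.p_target, "target", "distractor")
    if spec.hold_time_distributions is not None:
        mu_t, sig_t = spec.hold_time_distributions["target"]
        mu_d, sig_d = spec.hold_time_distributions["distractor"]
    else:
        mu_t = _calibrated_lognormal_mu(spec.stop_prob_target, spec.hold_threshold, spec.hold_sigma)
        mu_d = _calibrated_lognormal_mu(
            spec.stop_prob_distractor, spec.hold_threshold, spec.hold_sigma
        )
        sig_t = sig_d = spec.hold_sigma
    mu = np.where(stimulus == "target", mu_t, mu_d)
    sig = np.where(stimulus == "target", sig_t, sig_d)
    hold = np.exp(rng.normal(mu, sig))
    trials = pd.DataFrame(
        {
            "trial_id": np.arange(spec.n_trials),
            "stimulus": stimulus,
            "orientation": np.where(stimulus == "target", 90.0, 45.0),
            "hold_time": hold,
            "led": "off",
            "led_onset_ms": np.nan,
            "stop": hold >= spec.hold_threshold,
        }
    )
    return validate_trial_table(trials)


def generate_lfp(spec: LfpSpec, seed: int) -> LfpBlock:
    """Trial-averaged LFP: band-limited Gaussian noise plus a smooth
    negative-going deflection of ``deflection_amplitude`` × noise SD starting
    at ``deflection_onset_ms`` (alpha-function rise).  The ground-truth onset
    is recorded in the block metadata (absent when the amplitude is zero)."""
    spec.validate()
    rng = np.random.default_rng(seed)
    lo, hi = spec.span_ms
    n = int(round((hi - lo) / 1000.0 * spec.fs)) + 1
    t_ms = lo + np.arange(n) / spec.fs * 1000.0

    noise = rng.standard_normal((spec.n_channels, n))
    if spec.noise_bandwidth_hz < spec.fs / 2:
        from scipy import signal as _sig

        sos = _sig.butter(4, spec.noise_bandwidth_hz, btype="low", fs=spec.fs, output="sos")
        noise = _sig.sosfiltfilt(sos, noise, axis=-1)
    sd = noise.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    noise = noise / sd * spec.noise_sd

    rel = (t_ms - spec.deflection_onset_ms) / spec.deflection_tau_ms
    shape = np.where(rel > 0, rel * np.exp(1.0 - rel), 0.0)  # peak 1 at rel == 1
    deflection = -spec.deflection_amplitude * spec.noise_sd * shape
    traces = noise + deflection[None, :]
    return LfpBlock(
        traces=traces,
        fs=spec.fs,
        t_start=lo / 1000.0,
        ground_truth_onset_ms=(spec.deflection_onset_ms if spec.deflection_amplitude > 0 else None),
    )


def generate_passive(
    spec: PopulationSpec,
    seed: int,
    preferred_deg: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Passive-viewing responses: unit × orientation × repetition counts.

    Each unit's mean count over the analysis window follows a circular
    Gaussian (von-Mises-shaped, period 180°) over orientation, centered on
    its assigned preferred orientation; counts are Poisson.  Preferred
    orientations are drawn uniformly on [0, 180) unless supplied (the
    pipeline supplies task-role-aligned ones).  Returns ``(responses,
    truth)`` where truth records each unit's assigned preference.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    thetas = np.arange(spec.passive_n_orientations) * (180.0 / spec.passive_n_orientations)
    if preferred_deg is None:
        preferred_deg = rng.uniform(0.0, 180.0, size=spec.n_units)
    preferred_deg = np.asarray(preferred_deg, dtype=float) % 180.0
    if preferred_deg.size != spec.n_units:
        raise ValidationError("preferred_deg must have one entry per unit")

    window_s = spec.passive_window_ms / 1000.0
    rows = []
    for i in range(spec.n_units):
        delta = np.deg2rad(2.0 * (thetas - preferred_deg[i]))
        rate = spec.passive_baseline_rate_hz + spec.passive_peak_rate_hz * np.exp(
            spec.tuning_kappa * (np.cos(delta) - 1.0)
        )
        lam = rate * window_s
        counts = rng.poisson(lam[:, None], size=(thetas.size, spec.passive_n_reps))
        for k, theta in enumerate(thetas):
            for rep in range(spec.passive_n_reps):
                rows.append(
                    {
                        "unit_id": f"u{i:03d}",
                        "orientation_deg": float(theta),
                        "repetition": rep,
                        "count": int(counts[k, rep]),
                    }
                )
    truth = pd.DataFrame(
        {
            "unit_id": [f"u{i:03d}" for i in range(spec.n_units)],
            "preferred_orientation_deg": preferred_deg,
        }
    )
    return pd.DataFrame(rows), truth
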