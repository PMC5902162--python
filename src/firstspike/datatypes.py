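"""Core in-memory containers shared across the pipeline.

Trial tables are plain pandas DataFrames with a documented schema (see
:data:`TRIAL_REQUIRED_COLUMNS`); spike recordings and LFP blocks are small
dataclasses.  All times are stored in seconds relative to stimulus onset and
reported in milliseconds; every analysis window is half-open ``[start, end)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

#: Columns every trial table must carry.  ``stop`` is derived and optional on
#: input; ``orientation`` (degrees) and ``led_onset_ms`` are optional.
TRIAL_REQUIRED_COLUMNS = ("trial_id", "stimulus", "hold_time", "led")

STIMULI = ("target", "distractor")
LED_STATES = ("off", "on")


def validate_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table against the documented schema.

    Returns the table unchanged.  Raises :class:`SchemaError` naming any
    missing column, or :class:`ValidationError` with the offending row index
    for value-level violations (negative hold time, unknown stimulus, an LED
    onset on an LED-off trial, ...).
    """
    for col in TRIAL_REQUIRED_COLUMNS:
        if col not in trials.columns:
            raise SchemaError(f"trial table is missing required column {col!r}")
    bad_stim = ~trials["stimulus"].isin(STIMULI)
    if bad_stim.any():
        idx = trials.index[bad_stim][0]
        raise ValidationError(
            f"row {idx}: stimulus {trials.loc[idx, 'stimulus']!r} not in {STIMULI}"
        )
    neg = trials["hold_time"] < 0
    if neg.any():
        idx = trials.index[neg][0]
        raise ValidationError(f"row {idx}: negative hold time {trials.loc[idx, 'hold_time']}")
    bad_led = ~trials["led"].isin(LED_STATES)
    if bad_led.any():
        idx = trials.index[bad_led][0]
        raise ValidationError(f"row {idx}: led {trials.loc[idx, 'led']!r} not in {LED_STATES}")
    if "led_onset_ms" in trials.columns:
        on = trials["led"] == "on"
        missing = on & trials["led_onset_ms"].isna()
        spurious = ~on & trials["led_onset_ms"].notna()
        if missing.any():
            raise ValidationError(
                f"row {missing.idxmax()}: led is 'on' but led_onset_ms is absent"
            )
        if spurious.any():
            raise ValidationError(
                f"row {spurious.idxmax()}: led_onset_ms given on an led-off trial"
            )
    elif (trials["led"] == "on").any():
        raise SchemaError("led 'on' trials present but no led_onset_ms column")
    if trials["trial_id"].duplicated().any():
        raise ValidationError("duplicate trial_id values")
    return trials


@dataclass
class UnitRecording:
    """Trial-aligned spike times for one sorted unit.

    ``spikes`` maps trial id to a sorted float array of spike times in
    seconds relative to stimulus onset.
    """

    unit_id: str
    spikes: dict[int, np.ndarray]
    putative_type: str | None = None  # {"regular", "fast-spiking"}
    layer: int | None = None

    def __post_init__(self) -> None:
        clean: dict[int, np.ndarray] = {}
        for trial_id, times in self.spikes.items():
            arr = np.asarray(times, dtype=float)
            if arr.ndim != 1:
                raise ValidationError(
                    f"unit {self.unit_id}, trial {trial_id}: spike times must be 1-D"
                )
            if arr.size > 1 and np.any(np.diff(arr) < 0):
                warnings.warn(
                    f"unit {self.unit_id}, trial {trial_id}: spike times were "
                    "unsorted; normalizing",
                    stacklevel=2,
                )
                arr = np.sort(arr)
            clean[int(trial_id)] = arr
        self.spikes = clean

    @property
    def trial_ids(self) -> list[int]:
        return list(self.spikes.keys())

    @property
    def n_trials(self) -> int:
        return len(self.spikes)

    def check_trials(self, trials: pd.DataFrame) -> None:
        """Raise if any spike-train trial id is absent from ``trials``."""
        known = set(trials["trial_id"].astype(int))
        unknown = [t for t in self.spikes if t not in known]
        if unknown:
            raise ValidationError(
                f"unit {self.unit_id}: unknown trial ids {unknown[:5]}"
            )


@dataclass
class LfpBlock:
    """Trial-averaged LFP, one row per channel.

    Sample ``i`` sits at time ``t_start + i / fs`` seconds relative to
    stimulus onset (time 0).
    """

    traces: np.ndarray  # (n_channels, n_samples) volts
    fs: float  # Hz
    t_start: float  # s, time of first sample relative to stimulus onset
    ground_truth_onset_ms: float | None = None  # synthetic blocks only

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.fs <= 0:
            raise ValidationError("fs must be positive")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return self.t_start + np.arange(self.traces.shape[1]) / self.fs

    @property
    def n_channels(self) -> int:
        return self.traces.shape[0]


@dataclass
class OnsetResult:
    """Cortical response onset detected from a trial-averaged LFP block."""

    onset_ms: float | None  # ms from stimulus onset; None when never detected
    channel: int | None  # index of the earliest-crossing channel
    baseline_sd: np.ndarray = field(default_factory=lambda: np.array([]))
    per_channel_onset_ms: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def detected(self) -> bool:
        return self.onset_ms is not None
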