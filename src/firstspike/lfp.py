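"""Cortical response onset detection from trial-averaged LFP traces.

The trace is zero-phase low-pass filtered (4th-order Butterworth, 300 Hz,
applied forward and backward), the per-channel baseline mean and SD are taken
over [-80, +20) ms around stimulus onset, and the onset is the earliest
post-stimulus sample at which the filtered trace deviates from the baseline
mean by more than 3 SD — sign-agnostic, since the evoked deflection may be of
either polarity depending on the recording site.  A crossing must be
sustained for ``min_duration_ms`` (default 20 ms, a few correlation times of
trial-averaged LFP noise) to count, which rejects the brief noise excursions
a single-sample rule would accept while leaving the reported onset at the
first sample of the sustained run; set it to 0 for the bare threshold rule.  The per-channel onsets are minimized over channels and the
winning channel is reported.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .datatypes import LfpBlock, OnsetResult
from .errors import ValidationError

__all__ = ["lowpass_filter", "detect_onset"]

LOWPASS_CUTOFF_HZ = 300.0
BASELINE_WINDOW_MS = (-80.0, 20.0)
SEARCH_WINDOW_MS = (0.0, 300.0)


def lowpass_filter(trace: np.ndarray, fs: float, cutoff: float = LOWPASS_CUTOFF_HZ, order: int = 4) -> np.ndarray:
    """Zero-phase (bidirectional) Butterworth low-pass; length-preserving.

    Note the two passes square the magnitude response, so a sinusoid at the
    cutoff frequency comes out at half amplitude, not 1/sqrt(2).
    """
    if fs <= 2 * cutoff:
        raise ValidationError(f"sampling rate {fs} Hz must exceed twice the {cutoff} Hz cutoff")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(trace, dtype=float), axis=-1)


def detect_onset(
    block: LfpBlock,
    threshold_sd: float = 3.0,
    baseline_ms: tuple[float, float] = BASELINE_WINDOW_MS,
    search_ms: tuple[float, float] = SEARCH_WINDOW_MS,
    min_duration_ms: float = 20.0,
    cutoff: float = LOWPASS_CUTOFF_HZ,
) -> OnsetResult:
    """Earliest 3-SD deflection of the filtered trace, minimized over channels."""
    times_ms = block.times * 1000.0
    b0, b1 = baseline_ms
    if times_ms[0] > b0 or times_ms[-1] < search_ms[1]:
        raise ValidationError(
            f"trace span [{times_ms[0]:.1f}, {times_ms[-1]:.1f}] ms must cover "
            f"the baseline window and the search horizon"
        )
    filtered = lowpass_filter(block.traces, block.fs, cutoff=cutoff)
    baseline = (times_ms >= b0) & (times_ms < b1)
    search = (times_ms > search_ms[0]) & (times_ms <= search_ms[1])
    search_idx = np.nonzero(search)[0]
    min_run = max(1, int(round(min_duration_ms * block.fs / 1000.0)))

    baseline_sd = filtered[:, baseline].std(axis=1, ddof=1)
    per_channel = np.full(block.n_channels, np.nan)
    for ch in range(block.n_channels):
        mean = filtered[ch, baseline].mean()
        sd = baseline_sd[ch]
        if sd == 0:
            continue  # flat noiseless baseline: no finite threshold, no onset
        above = np.abs(filtered[ch, search_idx] - mean) > threshold_sd * sd
        onset_idx = _first_sustained(above, min_run)
        if onset_idx is not None:
            per_channel[ch] = times_ms[search_idx[onset_idx]]

    if np.all(np.isnan(per_channel)):
        return OnsetResult(None, None, baseline_sd, per_channel)
    channel = int(np.nanargmin(per_channel))
    return OnsetResult(float(per_channel[channel]), channel, baseline_sd, per_channel)


def _first_sustained(mask: np.ndarray, min_run: int) -> int | None:
    """Index of the first run of at least ``min_run`` consecutive True values."""
    if min_run <= 1:
        hits = np.nonzero(mask)[0]
        return int(hits[0]) if hits.size else None
    padded = np.concatenate([[0], mask.astype(int), [0]])
    diff = np.diff(padded)
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            return int(s)
    return None
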