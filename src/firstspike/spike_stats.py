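"""First-spike latency statistics, Poisson count modelling and PSTHs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import UnitRecording
from .errors import ValidationError

__all__ = [
    "first_spike_latencies",
    "latency_difference_test",
    "paired_latency_differences",
    "PoissonFit",
    "poisson_fit",
    "count_to_rate",
    "psth",
    "bootstrap_median_se",
]


def first_spike_latencies(
    unit: UnitRecording,
    onset_ms: float,
    horizon_ms: float = 300.0,
    trial_ids=None,
) -> tuple[np.ndarray, float]:
    """Per-trial first-spike latencies (ms from cortical onset).

    Only trials with at least one spike in ``(onset, onset + horizon]`` are
    counted; spike-free trials are omitted, not zero-filled.  Returns
    ``(latencies_ms, fraction_of_trials_omitted)``.
    """
    t0 = onset_ms / 1000.0
    t1 = (onset_ms + horizon_ms) / 1000.0
    ids = unit.trial_ids if trial_ids is None else trial_ids
    latencies = []
    for trial in ids:
        spk = unit.spikes[int(trial)]
        inside = spk[(spk > t0) & (spk <= t1)]
        if inside.size:
            latencies.append((inside[0] - t0) * 1000.0)
    n = len(ids)
    omitted = 1.0 - len(latencies) / n if n else float("nan")
    return np.asarray(latencies, dtype=float), omitted


def paired_latency_differences(
    units: list[UnitRecording],
    trials: pd.DataFrame,
    onset_ms: float,
    preferences: pd.Series,
    horizon_ms: float = 300.0,
) -> pd.DataFrame:
    """Per-unit mean first-spike latency for preferred vs non-preferred stimulus.

    Units lacking latencies for either stimulus are dropped.  Columns:
    unit_id, mean_latency_preferred_ms, mean_latency_nonpreferred_ms, diff_ms
    (preferred minus non-preferred; negative when the preferred stimulus is
    answered earlier).
    """
    is_target = trials["stimulus"] == "target"
    target_ids = trials.loc[is_target, "trial_id"].astype(int).tolist()
    distractor_ids = trials.loc[~is_target, "trial_id"].astype(int).tolist()
    rows = []
    for unit in units:
        pref = preferences.get(unit.unit_id)
        if pref is None:
            continue
        pref_ids, other_ids = (
            (target_ids, distractor_ids) if pref == "target" else (distractor_ids, target_ids)
        )
        lat_pref, _ = first_spike_latencies(unit, onset_ms, horizon_ms, pref_ids)
        lat_other, _ = first_spike_latencies(unit, onset_ms, horizon_ms, other_ids)
        if lat_pref.size == 0 or lat_other.size == 0:
            continue
        rows.append(
            {
                "unit_id": unit.unit_id,
                "mean_latency_preferred_ms": lat_pref.mean(),
                "mean_latency_nonpreferred_ms": lat_other.mean(),
                "diff_ms": lat_pref.mean() - lat_other.mean(),
            }
        )
    return pd.DataFrame(rows)


def latency_difference_test(differences) -> tuple[float, float]:
    """One-sample two-sided t-test that per-unit latency differences are zero.

    ``differences`` are per-unit (preferred - non-preferred) mean first-spike
    latencies in ms.  Returns (mean difference, p).
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValidationError("need latency differences from at least 2 units")
    if np.allclose(d, 0):
        return 0.0, 1.0
    res = stats.ttest_1samp(d, 0.0)
    return float(d.mean()), float(res.pvalue)


@dataclass
class PoissonFit:
    lam: float  # mean count per window
    support: np.ndarray  # bins 0..max(count)
    empirical: np.ndarray  # observed proportions per bin
    predicted: np.ndarray  # Poisson pmf at lam per bin
    r2: float  # variance explained across bins


def poisson_fit(counts) -> PoissonFit:
    """Fit the mean-matched Poisson and score it by variance explained.

    lambda is the sample mean; the predicted pmf is evaluated on the observed
    support 0..max(count); R^2 compares empirical bin proportions with the
    pmf.  A degenerate support (all counts equal) with zero residuals scores
    R^2 = 1.
    """
    c = np.asarray(counts)
    if c.size < 1:
        raise ValidationError("need at least one count")
    if np.any(c < 0) or not np.allclose(c, np.round(c)):
        raise ValidationError("counts must be non-negative integers")
    c = c.astype(int)
    lam = float(c.mean())
    support = np.arange(c.max() + 1)
    empirical = np.bincount(c, minlength=support.size) / c.size
    predicted = stats.poisson.pmf(support, lam)
    ss_res = float(np.sum((empirical - predicted) ** 2))
    ss_tot = float(np.sum((empirical - empirical.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return PoissonFit(lam=lam, support=support, empirical=empirical, predicted=predicted, r2=r2)


def count_to_rate(mean_count: float, window_ms: float) -> float:
    """Mean spike count per window -> firing rate in Hz."""
    if window_ms <= 0:
        raise ValidationError("window_ms must be positive")
    return mean_count / (window_ms / 1000.0)


def psth(
    units,
    trials: pd.DataFrame,
    bin_ms: float = 25.0,
    span_ms: tuple[float, float] = (-100.0, 300.0),
) -> pd.DataFrame:
    """Peristimulus time histogram: mean spike count per bin and stimulus.

    Bins are half-open ``[left, left + bin)`` aligned to stimulus onset; the
    mean is across all trials (and units, when a list is given) of each
    stimulus class.  Columns: bin_left_ms, stimulus, mean_count.
    """
    if bin_ms <= 0:
        raise ValidationError("bin_ms must be positive")
    if np.isscalar(units) or isinstance(units, UnitRecording):
        units = [units]
    lo, hi = span_ms
    edges_ms = np.arange(lo, hi + bin_ms / 2, bin_ms)
    edges_s = edges_ms / 1000.0
    rows = []
    for stimulus, sub in trials.groupby("stimulus"):
        ids = sub["trial_id"].astype(int).tolist()
        hist = np.zeros(edges_ms.size - 1)
        n = 0
        for unit in units:
            for trial in ids:
                spk = unit.spikes[int(trial)]
                hist += np.histogram(spk, bins=edges_s)[0]
                n += 1
        for left, mean in zip(edges_ms[:-1], hist / max(n, 1)):
            rows.append({"bin_left_ms": float(left), "stimulus": stimulus, "mean_count": float(mean)})
    return pd.DataFrame(rows)


def bootstrap_median_se(values, n_boot: int = 1000, rng=None) -> float:
    """Bootstrap standard error of the median (the convention used for all
    median +/- SE summaries in this package)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        return float("nan")
    rng = np.random.default_rng(rng)
    medians = np.median(
        x[rng.integers(0, x.size, size=(n_boot, x.size))], axis=1
    )
    return float(medians.std(ddof=1))
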