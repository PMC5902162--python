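"""Per-unit windowed ROC discrimination of target vs distractor spike counts.

For each unit, spike counts are taken in half-open windows ``[onset, onset +
interval)`` anchored at the cortical response onset.  Discriminability is the
cross-pair AUC between the target and distractor count distributions,
oriented by the unit's preference (sign of the mean-count difference over the
defining 300 ms window, ties broken toward target) so that values >= 0.5 mean
"better than chance".  Significance is a two-sided Wilcoxon rank-sum test on
the raw counts; the family of per-unit p-values at the 300 ms window passes
through Benjamini–Hochberg step-up selection, whose data-dependent effective
cutoff is reused for the earlier intervals when asking *when* a discriminating
unit starts to discriminate.  Units firing fewer than one spike every six
trials over the initial 300 ms are excluded before any of this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import ideal_observer_auc
from .datatypes import UnitRecording
from .errors import ValidationError

__all__ = [
    "count_in_window",
    "unit_auc",
    "bh_select",
    "exclusion_filter",
    "first_spike_reduce",
    "DiscriminationResult",
    "discrimination_curve",
]

#: Exclusion threshold: fewer than one spike every six trials (spikes/trial).
LOW_RATE_THRESHOLD = 1.0 / 6.0
DEFINING_INTERVAL_MS = 300.0


def count_in_window(
    unit: UnitRecording,
    onset_ms: float,
    interval_ms: float,
    trial_ids=None,
) -> np.ndarray:
    """Spike counts per trial in ``[onset, onset + interval)`` (half-open).

    ``trial_ids`` selects and orders the trials; defaults to the unit's own
    trial order.
    """
    if interval_ms <= 0:
        raise ValidationError("interval_ms must be positive")
    t0 = onset_ms / 1000.0
    t1 = (onset_ms + interval_ms) / 1000.0
    ids = unit.trial_ids if trial_ids is None else trial_ids
    counts = np.empty(len(ids), dtype=int)
    for i, trial in enumerate(ids):
        spk = unit.spikes[int(trial)]
        counts[i] = int(np.searchsorted(spk, t1, "left") - np.searchsorted(spk, t0, "left"))
    return counts


def unit_auc(counts_preferred, counts_other) -> tuple[float, float]:
    """(AUC, p): midrank cross-pair AUC and two-sided rank-sum p on counts.

    Spike counts are heavily tied, so the p-value always uses the normal
    approximation with tie correction.
    """
    x = np.asarray(counts_preferred, dtype=float)
    y = np.asarray(counts_other, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both count samples must be non-empty")
    auc = ideal_observer_auc(x, y)
    p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)
    return auc, p


def bh_select(pvals, fdr: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini–Hochberg step-up selection.

    Sort p ascending, find the largest i with ``p_(i) <= (i/m) * fdr`` and
    flag everything at or below that ``p_(i)``.  Returns ``(flags,
    effective_cutoff)``; the cutoff is NaN when nothing is selected.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), float("nan")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if not 0 < fdr < 1:
        raise ValidationError("fdr must lie in (0, 1)")
    order = np.argsort(p, kind="stable")
    m = p.size
    thresholds = (np.arange(1, m + 1) / m) * fdr
    passing = np.nonzero(p[order] <= thresholds)[0]
    if passing.size == 0:
        return np.zeros(m, dtype=bool), float("nan")
    cutoff = float(p[order][passing[-1]])
    return p <= cutoff, cutoff


def exclusion_filter(
    units: list[UnitRecording],
    onset_ms: float,
    window_ms: float = DEFINING_INTERVAL_MS,
    threshold: float = LOW_RATE_THRESHOLD,
) -> tuple[list[UnitRecording], list[str]]:
    """Drop low-rate units: mean count over ``[onset, onset+300 ms)`` < 1/6.

    Returns (retained units, excluded unit ids).  The mean pools all trials
    regardless of stimulus.
    """
    retained, excluded = [], []
    for unit in units:
        mean_count = count_in_window(unit, onset_ms, window_ms).mean() if unit.n_trials else 0.0
        (excluded if mean_count < threshold else retained).append(unit)
    return retained, [u.unit_id for u in excluded]


def first_spike_reduce(unit: UnitRecording, onset_ms: float) -> UnitRecording:
    """Keep at most each trial's first spike at or after the cortical onset.

    Baseline spikes before the onset are removed entirely, so downstream
    windowed counts are 0 or 1 everywhere.
    """
    t0 = onset_ms / 1000.0
    reduced = {}
    for trial, spk in unit.spikes.items():
        post = spk[spk >= t0]
        reduced[trial] = post[:1].copy()
    return UnitRecording(unit.unit_id, reduced, unit.putative_type, unit.layer)


@dataclass
class DiscriminationResult:
    """Per-unit, per-interval ROC table plus the fraction-discriminating curve."""

    table: pd.DataFrame  # unit_id, interval_ms, auc, p, discriminating_at
    fractions: pd.DataFrame  # interval_ms, fraction of discriminating units
    preferences: pd.Series  # unit_id -> {"target", "distractor"}
    discriminating: list[str] = field(default_factory=list)
    effective_cutoff: float = float("nan")
    fdr: float = 0.05

    @property
    def n_discriminating(self) -> int:
        return len(self.discriminating)


def _split_trial_ids(trials: pd.DataFrame) -> tuple[list[int], list[int]]:
    is_target = trials["stimulus"] == "target"
    return (
        trials.loc[is_target, "trial_id"].astype(int).tolist(),
        trials.loc[~is_target, "trial_id"].astype(int).tolist(),
    )


def discrimination_curve(
    units: list[UnitRecording],
    trials: pd.DataFrame,
    onset_ms: float,
    interval_grid=None,
    fdr: float = 0.05,
) -> DiscriminationResult:
    """Windowed ROC analysis across an interval grid.

    A unit is *discriminating* when its 300 ms rank-sum p-value survives BH
    selection across units; it counts as discriminating *at* an earlier
    interval when its raw p there falls below the same effective cutoff, so
    the fraction at 300 ms is 1 by construction.
    """
    if interval_grid is None:
        interval_grid = list(range(20, 320, 20))
    grid = [float(t) for t in interval_grid]
    if DEFINING_INTERVAL_MS not in grid:
        raise ValidationError("interval grid must contain the defining 300 ms window")
    if any(t <= 0 for t in grid) or np.any(np.diff(grid) <= 0):
        raise ValidationError("interval grid must be strictly increasing and positive")
    target_ids, distractor_ids = _split_trial_ids(trials)
    if not target_ids or not distractor_ids:
        raise ValidationError("need trials of both stimuli")

    rows = []
    preferences = {}
    p300 = {}
    for unit in units:
        c_t_300 = count_in_window(unit, onset_ms, DEFINING_INTERVAL_MS, target_ids)
        c_d_300 = count_in_window(unit, onset_ms, DEFINING_INTERVAL_MS, distractor_ids)
        # ties in the mean break toward target
        pref = "target" if c_t_300.mean() >= c_d_300.mean() else "distractor"
        preferences[unit.unit_id] = pref
        for interval in grid:
            c_t = count_in_window(unit, onset_ms, interval, target_ids)
            c_d = count_in_window(unit, onset_ms, interval, distractor_ids)
            if pref == "target":
                auc, p = unit_auc(c_t, c_d)
            else:
                auc, p = unit_auc(c_d, c_t)
            rows.append(
                {
                    "unit_id": unit.unit_id,
                    "interval_ms": interval,
                    "auc": auc,
                    "p": p,
                    "mean_count_target": c_t.mean(),
                    "mean_count_distractor": c_d.mean(),
                }
            )
            if interval == DEFINING_INTERVAL_MS:
                p300[unit.unit_id] = p
    table = pd.DataFrame(rows)

    unit_ids = [u.unit_id for u in units]
    flags, cutoff = bh_select([p300[u] for u in unit_ids], fdr)
    discriminating = [u for u, keep in zip(unit_ids, flags) if keep]
    disc_set = set(discriminating)
    table["significant"] = table["unit_id"].isin(disc_set) & (
        table["p"] <= (cutoff if np.isfinite(cutoff) else -np.inf)
    )

    fractions = []
    for interval in grid:
        sub = table[(table["interval_ms"] == interval) & table["unit_id"].isin(disc_set)]
        frac = float(sub["significant"].mean()) if len(sub) else float("nan")
        fractions.append({"interval_ms": interval, "fraction_discriminating": frac})

    return DiscriminationResult(
        table=table,
        fractions=pd.DataFrame(fractions),
        preferences=pd.Series(preferences, name="preference"),
        discriminating=discriminating,
        effective_cutoff=cutoff,
        fdr=fdr,
    )
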