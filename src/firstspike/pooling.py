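"""Population pooling: how many neurons explain the behavioral accuracy.

The pool of recorded units is enlarged by *shuffle augmentation*: each source
unit contributes ``n_copies`` surrogate units whose trials are permuted
within stimulus class, preserving every single-unit stimulus-conditioned
statistic while breaking cross-unit noise correlations.  Units preferring the
distractor have their target and distractor responses swapped so every pooled
unit is oriented the same way.  A *pooling neuron* for a sample of N units
carries, per trial, the summed spike counts of the N units; its cross-pair
AUC is averaged over ``n_samples`` random samples, and the whole procedure is
repeated ``n_repeats`` times to attach an SEM.  The readout is the smallest N
whose mean AUC reaches a supplied behavioral accuracy (as a proportion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import ideal_observer_auc
from .datatypes import UnitRecording
from .discrimination import count_in_window
from .errors import ValidationError

__all__ = [
    "AugmentedPool",
    "augment",
    "flip_preference",
    "class_count_matrices",
    "pooled_auc",
    "PoolingCurve",
    "pooling_curve",
]

DEFAULT_POOL_SIZES = (2, 5, 10, 20, 50, 100, 200)


def _class_trial_ids(trials: pd.DataFrame) -> tuple[list[int], list[int]]:
    is_target = trials["stimulus"] == "target"
    return (
        trials.loc[is_target, "trial_id"].astype(int).tolist(),
        trials.loc[~is_target, "trial_id"].astype(int).tolist(),
    )


@dataclass
class AugmentedPool:
    units: list[UnitRecording]
    provenance: pd.DataFrame  # pooled unit id -> source unit id, copy index

    def __len__(self) -> int:
        return len(self.units)


def augment(
    units: list[UnitRecording],
    trials: pd.DataFrame,
    n_copies: int = 6,
    seed: int | np.random.Generator = 0,
    within_class: bool = True,
) -> AugmentedPool:
    """Enlarge the pool with trial-shuffled surrogate copies of each unit.

    Each copy independently permutes trial assignments — within stimulus
    class by default (target trials shuffled among target trials, distractor
    among distractor), or unrestricted with ``within_class=False``.  The pool
    holds ``(n_copies + 1) * len(units)`` units; copy index 0 is the
    original.
    """
    if n_copies < 0:
        raise ValidationError("n_copies must be >= 0")
    rng = np.random.default_rng(seed)
    target_ids, distractor_ids = _class_trial_ids(trials)
    pooled, rows = [], []
    for unit in units:
        pooled.append(unit)
        rows.append({"pooled_id": unit.unit_id, "source_id": unit.unit_id, "copy": 0})
        for c in range(1, n_copies + 1):
            if within_class:
                mapping = {}
                for ids in (target_ids, distractor_ids):
                    perm = rng.permutation(len(ids))
                    mapping.update({ids[i]: ids[perm[i]] for i in range(len(ids))})
            else:
                ids = target_ids + distractor_ids
                perm = rng.permutation(len(ids))
                mapping = {ids[i]: ids[perm[i]] for i in range(len(ids))}
            spikes = {t: unit.spikes[mapping[t]].copy() for t in mapping}
            copy_id = f"{unit.unit_id}#s{c}"
            pooled.append(UnitRecording(copy_id, spikes, unit.putative_type, unit.layer))
            rows.append({"pooled_id": copy_id, "source_id": unit.unit_id, "copy": c})
    return AugmentedPool(units=pooled, provenance=pd.DataFrame(rows))


def flip_preference(unit: UnitRecording, trials: pd.DataFrame) -> UnitRecording:
    """Swap a unit's target and distractor responses (trial-class swap).

    The i-th target trial exchanges spike trains with the i-th distractor
    trial, which requires equal per-class trial counts.  Applying the flip
    twice restores the original unit.
    """
    target_ids, distractor_ids = _class_trial_ids(trials)
    if len(target_ids) != len(distractor_ids):
        raise ValidationError(
            "flip_preference needs equal target and distractor trial counts"
        )
    spikes = dict(unit.spikes)
    for t_id, d_id in zip(target_ids, distractor_ids):
        spikes[t_id], spikes[d_id] = unit.spikes[d_id].copy(), unit.spikes[t_id].copy()
    return UnitRecording(unit.unit_id, spikes, unit.putative_type, unit.layer)


def class_count_matrices(
    units: list[UnitRecording],
    trials: pd.DataFrame,
    onset_ms: float,
    window_ms: float,
    preferences: pd.Series | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(preferred-class, other-class) count matrices, one row per unit.

    When ``preferences`` are given, rows of distractor-preferring units are
    swapped so row sums across units always accumulate preferred-stimulus
    signal (the flip-preference step at matrix level).
    """
    target_ids, distractor_ids = _class_trial_ids(trials)
    T = np.stack([count_in_window(u, onset_ms, window_ms, target_ids) for u in units])
    D = np.stack([count_in_window(u, onset_ms, window_ms, distractor_ids) for u in units])
    if preferences is not None:
        for i, u in enumerate(units):
            source = u.unit_id.split("#")[0]  # surrogate copies inherit the source preference
            if preferences.get(source, "target") == "distractor":
                T[i], D[i] = D[i].copy(), T[i].copy()
    return T, D


def pooled_auc(
    pool_pref: np.ndarray,
    pool_other: np.ndarray,
    n: int,
    n_samples: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Mean AUC of the pooling neuron over random N-unit samples.

    Units are sampled without replacement; the pooling neuron's per-trial
    count is the sum of the sampled units' counts (trials aligned by index
    within class).
    """
    pool_pref = np.asarray(pool_pref)
    pool_other = np.asarray(pool_other)
    n_units = pool_pref.shape[0]
    if not 1 <= n <= n_units:
        raise ValidationError(f"pool size N={n} must lie in [1, {n_units}]")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_samples)
    for s in range(n_samples):
        idx = rng.choice(n_units, size=n, replace=False)
        aucs[s] = ideal_observer_auc(pool_pref[idx].sum(axis=0), pool_other[idx].sum(axis=0))
    return float(aucs.mean())


@dataclass
class PoolingCurve:
    ns: list[int]
    mean_auc: np.ndarray
    sem: np.ndarray  # across procedure repetitions
    n_samples: int
    n_repeats: int
    readout_n: int | None = None  # smallest N whose mean AUC reaches behavior
    behavior_accuracy: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"N": self.ns, "mean_auc": self.mean_auc, "sem": self.sem})


def pooling_curve(
    pool_pref: np.ndarray,
    pool_other: np.ndarray,
    ns=DEFAULT_POOL_SIZES,
    n_samples: int = 1000,
    n_repeats: int = 10,
    seed: int = 0,
    behavior_accuracy: float | None = None,
) -> PoolingCurve:
    """Mean ± SEM pooled AUC per pool size N over repeated procedures."""
    ns = [int(n) for n in ns if n <= np.asarray(pool_pref).shape[0]]
    if not ns:
        raise ValidationError("no pool size fits inside the pool")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_repeats)
    per_repeat = np.empty((n_repeats, len(ns)))
    for r in range(n_repeats):
        rng = np.random.default_rng(children[r])
        for j, n in enumerate(ns):
            per_repeat[r, j] = pooled_auc(pool_pref, pool_other, n, n_samples, rng)
    mean = per_repeat.mean(axis=0)
    sem = per_repeat.std(axis=0, ddof=1) / np.sqrt(n_repeats) if n_repeats > 1 else np.zeros(len(ns))
    readout = None
    if behavior_accuracy is not None:
        hits = [n for n, m in zip(ns, mean) if m >= behavior_accuracy]
        readout = min(hits) if hits else None
    return PoolingCurve(
        ns=ns,
        mean_auc=mean,
        sem=sem,
        n_samples=n_samples,
        n_repeats=n_repeats,
        readout_n=readout,
        behavior_accuracy=behavior_accuracy,
    )
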