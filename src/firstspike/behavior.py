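"""Behavioral readouts for the stop/no-stop discrimination task.

A trial is a *stop trial* when the stimulus is held in the reward zone for at
least the minimal hold time (boundary equality counts as a stop).  Accuracy is
the average of the per-class correct rates — percent stop trials on targets
and percent non-stop trials on distractors — so chance is 50% regardless of
the animal's overall stop rate.  The ideal-observer AUC asks how well the
*continuous* hold times separate the two stimuli, catching discrimination that
the binary stop classification misses.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import ValidationError

__all__ = [
    "classify_stops",
    "accuracy",
    "ideal_observer_auc",
    "choice_ranksum",
    "binomial_ci95",
    "BehaviorSummary",
    "behavior_summary",
]


def classify_stops(trials: pd.DataFrame, hold_threshold: float) -> pd.DataFrame:
    """Return a copy of ``trials`` with the derived ``stop`` flag.

    ``stop`` is true iff ``hold_time >= hold_threshold`` (the threshold itself
    counts as a stop).
    """
    if hold_threshold <= 0:
        raise ValidationError("hold_threshold must be positive")
    out = trials.copy()
    out["stop"] = out["hold_time"] >= hold_threshold
    return out


def accuracy(trials: pd.DataFrame) -> float:
    """Percent-correct: mean of stop%|target and non-stop%|distractor."""
    if "stop" not in trials.columns:
        raise ValidationError("trials lack a 'stop' column; run classify_stops first")
    is_target = trials["stimulus"] == "target"
    n_t = int(is_target.sum())
    n_d = int((~is_target).sum())
    for n, name in ((n_t, "target"), (n_d, "distractor")):
        if n == 0:
            raise ValidationError(f"no {name} trials; accuracy undefined")
    stop = trials["stop"].to_numpy(bool)
    p_stop_target = stop[is_target.to_numpy()].mean()
    p_nonstop_distractor = (~stop[~is_target.to_numpy()]).mean()
    return 100.0 * (p_stop_target + p_nonstop_distractor) / 2.0


def ideal_observer_auc(values_positive, values_negative) -> float:
    """Cross-pair AUC: P(pos > neg) + 0.5 P(pos = neg), via midranks.

    Used both for the behavioral ideal observer (hold times of target vs
    distractor trials) and, in the discrimination module, for spike counts.
    """
    x = np.asarray(values_positive, dtype=float)
    y = np.asarray(values_negative, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty for ROC analysis")
    ranks = stats.rankdata(np.concatenate([x, y]))
    u1 = ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0
    return float(u1 / (x.size * y.size))


def choice_ranksum(holds_target, holds_distractor) -> float:
    """Two-sided Wilcoxon rank-sum p-value on hold times.

    Exact permutation null for small tie-free samples (combined n <= 20),
    otherwise the normal approximation with tie correction.
    """
    x = np.asarray(holds_target, dtype=float)
    y = np.asarray(holds_distractor, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty for the rank-sum test")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def binomial_ci95(k: int, n: int) -> tuple[float, float]:
    """Exact (Clopper–Pearson) 95% confidence interval for a proportion."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValidationError("k must satisfy 0 <= k <= n")
    lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
    return float(lo), float(hi)


@dataclass
class BehaviorSummary:
    n_target: int
    n_distractor: int
    stop_prob_target: float
    stop_prob_target_ci: tuple[float, float]
    stop_prob_distractor: float
    stop_prob_distractor_ci: tuple[float, float]
    accuracy_percent: float
    ideal_observer_auc: float
    ranksum_p: float

    def to_dict(self) -> dict:
        return asdict(self)


def behavior_summary(trials: pd.DataFrame, hold_threshold: float) -> BehaviorSummary:
    """Full behavioral readout of one session's trial table."""
    t = classify_stops(trials, hold_threshold)
    is_target = (t["stimulus"] == "target").to_numpy()
    stop = t["stop"].to_numpy(bool)
    holds = t["hold_time"].to_numpy(float)
    k_t, n_t = int(stop[is_target].sum()), int(is_target.sum())
    k_d, n_d = int(stop[~is_target].sum()), int((~is_target).sum())
    if n_t == 0 or n_d == 0:
        raise ValidationError("need at least one target and one distractor trial")
    return BehaviorSummary(
        n_target=n_t,
        n_distractor=n_d,
        stop_prob_target=k_t / n_t,
        stop_prob_target_ci=binomial_ci95(k_t, n_t),
        stop_prob_distractor=k_d / n_d,
        stop_prob_distractor_ci=binomial_ci95(k_d, n_d),
        accuracy_percent=accuracy(t),
        ideal_observer_auc=ideal_observer_auc(holds[is_target], holds[~is_target]),
        ranksum_p=choice_ranksum(holds[is_target], holds[~is_target]),
    )
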