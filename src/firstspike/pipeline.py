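"""End-to-end synthetic pipeline: simulate a session, run every analysis
stage, and write all tables plus a JSON summary and run log.

Two runs with the same configuration and seed produce byte-identical
outputs: every stochastic stage draws from a child of one seed sequence, and
each stage's seed is recorded in the run log.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import discrimination as disc
from . import pooling as pool
from . import spike_stats as sps
from . import synthetic as syn
from . import tuning as tun
from .config import AnalysisConfig, save_config
from .errors import StageError
from .io import write_lfp, write_passive, write_trial_table, write_units
from .lfp import detect_onset

__all__ = ["RunLog", "run_pipeline"]


@dataclass
class RunLog:
    config: dict
    seed: int
    stage_seeds: dict = field(default_factory=dict)
    record_counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seed": self.seed,
                "stage_seeds": self.stage_seeds,
                "record_counts": self.record_counts,
                "warnings": self.warnings,
            },
            indent=1,
            sort_keys=True,
        )


def _stage(log: RunLog, name: str):
    class _Guard:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            return False

    return _Guard()


def run_pipeline(
    config: AnalysisConfig,
    out_dir: str | Path,
    seed: int | None = None,
    pop_spec: syn.PopulationSpec | None = None,
    lfp_spec: syn.LfpSpec | None = None,
    pooling_samples: int = 200,
    pooling_repeats: int = 5,
) -> dict:
    """Simulate one session and run the full analysis chain.

    Returns the summary dictionary that is also written to ``summary.json``.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ("population", "lfp", "passive", "pooling", "bootstrap"), ss.spawn(5)
        )
    }
    log = RunLog(config=config.to_dict(), seed=seed, stage_seeds=seeds)
    pop_spec = pop_spec or syn.PopulationSpec(fraction_nondiscriminating=0.3)
    lfp_spec = lfp_spec or syn.LfpSpec()
    summary: dict = {}

    with _stage(log, "simulate"):
        with warnings.catch_warnings(record=True) as caught:
            population = syn.generate_population(pop_spec, seeds["population"])
            lfp_spec.deflection_onset_ms = population.onset_ms
            lfp_block = syn.generate_lfp(lfp_spec, seeds["lfp"])
            preferred = np.where(
                population.unit_truth["preferred_stimulus"] == "target",
                np.random.default_rng(seeds["passive"]).normal(90.0, 8.0, len(population.units)),
                np.where(
                    population.unit_truth["preferred_stimulus"] == "distractor",
                    np.random.default_rng(seeds["passive"] + 1).normal(
                        45.0, 8.0, len(population.units)
                    ),
                    np.random.default_rng(seeds["passive"] + 2).uniform(
                        0.0, 180.0, len(population.units)
                    ),
                ),
            )
            passive, passive_truth = syn.generate_passive(
                pop_spec, seeds["passive"], preferred_deg=preferred
            )
        log.warnings.extend(str(w.message) for w in caught)
        write_trial_table(population.trials, out / "trials.csv")
        write_units(population.units, out / "units.jsonl")
        write_lfp(lfp_block, out / "lfp.csv")
        write_passive(passive, out / "passive.csv")
        log.record_counts["trials"] = len(population.trials)
        log.record_counts["units"] = len(population.units)

    with _stage(log, "behavior"):
        summary_b = bhv.behavior_summary(population.trials, config.hold_time_threshold)
        (out / "behavior_summary.json").write_text(
            json.dumps(summary_b.to_dict(), indent=1, sort_keys=True)
        )
        summary["behavior"] = summary_b.to_dict()

    with _stage(log, "onset"):
        onset = detect_onset(lfp_block)
        onset_ms = (
            config.cortical_onset_override
            if config.cortical_onset_override is not None
            else onset.onset_ms
        )
        if onset_ms is None:
            raise ValueError("no cortical onset detected and no override configured")
        (out / "onset.json").write_text(
            json.dumps(
                {
                    "onset_ms": onset.onset_ms,
                    "channel": onset.channel,
                    "used_onset_ms": onset_ms,
                    "ground_truth_onset_ms": lfp_block.ground_truth_onset_ms,
                },
                indent=1,
                sort_keys=True,
            )
        )
        summary["onset_ms"] = onset_ms

    with _stage(log, "discriminate"):
        retained, excluded = disc.exclusion_filter(
            population.units, onset_ms, threshold=config.exclusion_rate_threshold
        )
        log.record_counts["units_excluded_low_rate"] = len(excluded)
        result = disc.discrimination_curve(
            retained, population.trials, onset_ms, config.interval_grid, config.bh_fdr
        )
        result.table.to_csv(out / "discrimination.csv", index=False)
        result.fractions.to_csv(out / "fractions.csv", index=False)
        summary["discrimination"] = {
            "n_units_analyzed": len(retained),
            "n_excluded": len(excluded),
            "n_discriminating": result.n_discriminating,
            "fraction_discriminating": result.n_discriminating / max(len(retained), 1),
            "effective_bh_cutoff": result.effective_cutoff,
        }
        auc80 = result.table[result.table["interval_ms"] == 80.0].set_index("unit_id")["auc"]
        disc_ids = result.discriminating

    with _stage(log, "firstspike"):
        reduced = [disc.first_spike_reduce(u, onset_ms) for u in retained]
        fs_result = disc.discrimination_curve(
            reduced, population.trials, onset_ms, config.interval_grid, config.bh_fdr
        )
        fs_result.fractions.to_csv(out / "first_spike_fractions.csv", index=False)
        summary["first_spike"] = {
            "n_discriminating": fs_result.n_discriminating,
            "effective_bh_cutoff": fs_result.effective_cutoff,
        }

    with _stage(log, "latency"):
        disc_units = [u for u in retained if u.unit_id in disc_ids]
        diffs = sps.paired_latency_differences(
            disc_units,
            population.trials,
            onset_ms,
            result.preferences,
            config.first_spike_horizon,
        )
        diffs.to_csv(out / "latency_differences.csv", index=False)
        summary["latency"] = {"n_units": len(diffs)}
        if len(diffs) >= 2:
            mean_diff, p = sps.latency_difference_test(diffs["diff_ms"])
            rng_boot = np.random.default_rng(seeds["bootstrap"])
            summary["latency"].update(
                {
                    "mean_difference_ms": mean_diff,
                    "t_test_p": p,
                    "median_latency_preferred_ms": float(
                        diffs["mean_latency_preferred_ms"].median()
                    ),
                    "median_latency_preferred_se": sps.bootstrap_median_se(
                        diffs["mean_latency_preferred_ms"], rng=rng_boot
                    ),
                    "median_latency_nonpreferred_ms": float(
                        diffs["mean_latency_nonpreferred_ms"].median()
                    ),
                    "median_latency_nonpreferred_se": sps.bootstrap_median_se(
                        diffs["mean_latency_nonpreferred_ms"], rng=rng_boot
                    ),
                }
            )

    with _stage(log, "poisson"):
        target_ids = population.trials.loc[
            population.trials["stimulus"] == "target", "trial_id"
        ].astype(int).tolist()
        distractor_ids = population.trials.loc[
            population.trials["stimulus"] == "distractor", "trial_id"
        ].astype(int).tolist()
        fit_rows, all_counts = [], []
        for unit in disc_units:
            ids = target_ids if result.preferences[unit.unit_id] == "target" else distractor_ids
            counts = disc.count_in_window(unit, onset_ms, 80.0, ids)
            fit = sps.poisson_fit(counts)
            fit_rows.append({"unit_id": unit.unit_id, "lambda": fit.lam, "r2": fit.r2})
            all_counts.append(counts)
        pd.DataFrame(fit_rows).to_csv(out / "poisson_fits.csv", index=False)
        if all_counts:
            pooled_counts = np.concatenate(all_counts)
            mean_counts = np.array([c.mean() for c in all_counts])
            summary["counts_80ms"] = {
                "median_preferred_count": float(np.median(mean_counts)),
                "preferred_rate_hz": sps.count_to_rate(float(np.median(mean_counts)), 80.0),
                "fraction_trials_le1": float((pooled_counts <= 1).mean()),
                "fraction_trials_eq2": float((pooled_counts == 2).mean()),
                "fraction_trials_gt2": float((pooled_counts > 2).mean()),
                "fraction_units_gt2": float((mean_counts > 2).mean()),
                "median_poisson_r2": float(np.median([r["r2"] for r in fit_rows])),
            }

    with _stage(log, "tuning"):
        tuning_rows = []
        for unit_id, sub in passive.groupby("unit_id"):
            curve = tun.tuning_curve(sub, pop_spec.passive_window_ms)
            if curve.degenerate:
                tuning_rows.append(
                    {"unit_id": unit_id, "preferred_deg": float("nan"), "osi": float("nan")}
                )
                continue
            tuning_rows.append(
                {
                    "unit_id": unit_id,
                    "preferred_deg": tun.preferred_orientation(curve),
                    "osi": tun.osi(curve),
                }
            )
        tuning_table = pd.DataFrame(tuning_rows)
        tuning_table.to_csv(out / "tuning.csv", index=False)
        # passive Δspikes (90° − 45°) vs task AUC at 80 ms, discriminating units
        mean_counts_by_ori = passive.groupby(["unit_id", "orientation_deg"])["count"].mean()
        xs, ys = [], []
        for unit_id in disc_ids:
            if (unit_id, 90.0) in mean_counts_by_ori.index and (
                unit_id,
                45.0,
            ) in mean_counts_by_ori.index:
                xs.append(
                    mean_counts_by_ori[(unit_id, 90.0)] - mean_counts_by_ori[(unit_id, 45.0)]
                )
                # orient the AUC toward the target so it pairs with the signed Δcount
                sign = 1.0 if result.preferences[unit_id] == "target" else -1.0
                ys.append(0.5 + sign * (auc80[unit_id] - 0.5))
        if len(xs) >= 3 and np.ptp(xs) > 0:
            fit = tun.auc_vs_dspikes_fit(xs, ys)
            summary["auc_vs_dspikes"] = {
                "slope": fit.slope,
                "se_slope": fit.se_slope,
                "intercept": fit.intercept,
                "r2": fit.r2,
                "p_slope_positive": fit.p_slope_positive,
                "n": fit.n,
            }

    with _stage(log, "pooling"):
        if disc_units:
            augmented = pool.augment(
                disc_units, population.trials, n_copies=6, seed=seeds["pooling"]
            )
            T, D = pool.class_count_matrices(
                augmented.units, population.trials, onset_ms, 80.0, result.preferences
            )
            curve = pool.pooling_curve(
                T,
                D,
                n_samples=pooling_samples,
                n_repeats=pooling_repeats,
                seed=seeds["pooling"],
                behavior_accuracy=summary["behavior"]["accuracy_percent"] / 100.0,
            )
            curve.to_frame().to_csv(out / "pooling.csv", index=False)
            summary["pooling"] = {
                "pool_size": len(augmented),
                "ns": curve.ns,
                "mean_auc": [float(m) for m in curve.mean_auc],
                "sem": [float(s) for s in curve.sem],
                "neurons_to_explain_behavior": curve.readout_n,
            }
            log.record_counts["pool_size"] = len(augmented)

    summary_text = json.dumps(summary, indent=1, sort_keys=True)
    (out / "summary.json").write_text(summary_text)
    save_config(config, out / "effective_config.yaml")
    (out / "run_log.json").write_text(log.to_json())
    return summary
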