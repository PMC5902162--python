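"""Serialization of the pipeline's domain types.

Human-inspectable, diff-able formats throughout: trial tables are CSV with a
documented header; spike trains are JSON-lines (one unit per line, mapping
trial id to a spike-time array in seconds relative to stimulus onset); LFP
blocks are CSV (one column per channel) with a JSON sidecar carrying the
sampling rate and alignment; passive responses are long-format CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import LfpBlock, UnitRecording, validate_trial_table
from .errors import SchemaError

__all__ = [
    "read_trial_table",
    "write_trial_table",
    "read_units",
    "write_units",
    "read_lfp",
    "write_lfp",
    "read_passive",
    "write_passive",
]

_TRIAL_DTYPES = {"trial_id": int, "hold_time": float}


def read_trial_table(path: str | Path) -> pd.DataFrame:
    trials = pd.read_csv(path)
    for col, dtype in _TRIAL_DTYPES.items():
        if col in trials.columns:
            trials[col] = trials[col].astype(dtype)
    if "stop" in trials.columns:
        trials["stop"] = trials["stop"].astype(bool)
    return validate_trial_table(trials)


def write_trial_table(trials: pd.DataFrame, path: str | Path) -> None:
    validate_trial_table(trials)
    trials.to_csv(path, index=False)


def read_units(path: str | Path, trials: pd.DataFrame | None = None) -> list[UnitRecording]:
    """Read a JSON-lines unit file; cross-checks trial ids when given a table."""
    units = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            record = json.loads(line)
            if "unit_id" not in record or "trials" not in record:
                raise SchemaError(f"line {line_no}: unit records need 'unit_id' and 'trials'")
            unit = UnitRecording(
                unit_id=str(record["unit_id"]),
                spikes={int(t): np.asarray(s, dtype=float) for t, s in record["trials"].items()},
                putative_type=record.get("putative_type"),
                layer=record.get("layer"),
            )
            if trials is not None:
                unit.check_trials(trials)
            units.append(unit)
    return units


def write_units(units: list[UnitRecording], path: str | Path) -> None:
    with open(path, "w") as fh:
        for unit in units:
            record = {
                "unit_id": unit.unit_id,
                "putative_type": unit.putative_type,
                "layer": unit.layer,
                "trials": {str(t): [float(x) for x in s] for t, s in unit.spikes.items()},
            }
            fh.write(json.dumps(record) + "\n")


def _sidecar_path(csv_path: str | Path) -> Path:
    return Path(csv_path).with_suffix(".json")


def read_lfp(csv_path: str | Path, sidecar_path: str | Path | None = None) -> LfpBlock:
    sidecar_path = sidecar_path or _sidecar_path(csv_path)
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    for key in ("fs", "t_start_s"):
        if key not in meta:
            raise SchemaError(f"LFP sidecar is missing {key!r}")
    frame = pd.read_csv(csv_path)
    return LfpBlock(
        traces=frame.to_numpy(float).T,
        fs=float(meta["fs"]),
        t_start=float(meta["t_start_s"]),
        ground_truth_onset_ms=meta.get("ground_truth_onset_ms"),
    )


def write_lfp(block: LfpBlock, csv_path: str | Path, sidecar_path: str | Path | None = None) -> None:
    sidecar_path = sidecar_path or _sidecar_path(csv_path)
    frame = pd.DataFrame(block.traces.T, columns=[f"ch{i}" for i in range(block.n_channels)])
    frame.to_csv(csv_path, index=False)
    meta = {
        "fs": block.fs,
        "t_start_s": block.t_start,
        "ground_truth_onset_ms": block.ground_truth_onset_ms,
    }
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


_PASSIVE_COLUMNS = ("unit_id", "orientation_deg", "repetition", "count")


def read_passive(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    for col in _PASSIVE_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"passive response table is missing column {col!r}")
    return frame


def write_passive(responses: pd.DataFrame, path: str | Path) -> None:
    responses.to_csv(path, index=False)
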