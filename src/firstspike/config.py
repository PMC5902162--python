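"""Analysis configuration: YAML with full defaulting.

The effective (merged) configuration is always written alongside results so
a run can be reproduced from its output directory alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass
class AnalysisConfig:
    hold_time_threshold: float = 0.9  # s; minimal hold in the reward zone
    target_orientation: float = 90.0  # degrees
    distractor_orientation: float = 45.0
    cortical_onset_override: float | None = None  # ms; None = detect from LFP
    interval_grid: list[float] = field(default_factory=lambda: list(range(20, 320, 20)))
    bh_fdr: float = 0.05
    exclusion_rate_threshold: float = 1.0 / 6.0  # spikes/trial over 300 ms
    first_spike_horizon: float = 300.0  # ms
    rng_seed: int = 0

    def validate(self) -> "AnalysisConfig":
        if self.hold_time_threshold <= 0:
            raise ValidationError("hold_time_threshold must be positive")
        if not 0 < self.bh_fdr < 1:
            raise ValidationError("bh_fdr must lie in (0, 1)")
        grid = list(self.interval_grid)
        if not grid:
            raise ValidationError("interval_grid must be non-empty")
        if any(t <= 0 for t in grid) or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValidationError("interval_grid must be strictly increasing and positive")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> AnalysisConfig:
    """Build a config from defaults, an optional YAML file, then overrides."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        unknown = set(loaded) - set(AnalysisConfig.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return AnalysisConfig(**values).validate()


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
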