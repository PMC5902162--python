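import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from firstspike import PopulationSpec, UnitRecording, generate_population

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def small_trials() -> pd.DataFrame:
    """Six trials, three per stimulus, with hand-set hold times."""
    return pd.DataFrame(
        {
            "trial_id": [0, 1, 2, 3, 4, 5],
            "stimulus": ["target", "distractor", "target", "distractor", "target", "distractor"],
            "hold_time": [1.2, 0.1, 0.95, 0.3, 0.2, 1.1],
            "led": ["off"] * 6,
        }
    )


@pytest.fixture
def simple_unit() -> UnitRecording:
    """One unit over the six trials of ``small_trials`` with known spikes."""
    return UnitRecording(
        unit_id="u0",
        spikes={
            0: np.array([0.05, 0.10, 0.25]),
            1: np.array([0.07]),
            2: np.array([0.01, 0.05, 0.09]),
            3: np.array([]),
            4: np.array([0.12]),
            5: np.array([-0.05, 0.30]),
        },
    )


@pytest.fixture(scope="session")
def default_population():
    """A mid-sized synthetic session shared by read-only tests."""
    spec = PopulationSpec(n_units=30, n_trials_per_stimulus=60, fraction_nondiscriminating=0.2)
    return generate_population(spec, seed=123)
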