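"""Shared fixtures: synthetic landscapes and tracks built at test time."""

import numpy as np
import pandas as pd
import pytest

from carnmove.preprocess import Burst, steps_from_burst
from carnmove.synth import LandscapeSpec, TrackSpec, make_landscape, simulate_track


@pytest.fixture(scope="session")
def small_landscape():
    """128 x 128 cells at 10 m: fast, with all four cover classes."""
    return make_landscape(LandscapeSpec(grid_size=128, seed=42))


@pytest.fixture(scope="session")
def sim3():
    """A 2000-step, 3-state track with the study-scale movement states."""
    spec = TrackSpec(duration_days=2000 * 2 / 24.0, missingness=0.0, seed=11)
    fixes, states = simulate_track(spec, None)
    burst = Burst("sim", fixes[["timestamp", "x", "y", "source", "missing"]])
    steps = steps_from_burst(burst)
    return steps, states


def burst_from_fixes(fixes: pd.DataFrame) -> Burst:
    return Burst("sim", fixes[["timestamp", "x", "y", "source", "missing"]].reset_index(drop=True))
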