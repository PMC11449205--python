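import numpy as np
import pandas as pd
import pytest

from movenull import SimConfig, TrackingDataset


class FixedIntegerRng:
    """Stand-in RNG whose ``integers`` always returns a fixed value; used to
    force a specific wrap-around shift in oracle tests."""

    def __init__(self, value: int):
        self.value = value

    def integers(self, low, high):
        assert low <= self.value < high
        return self.value


def make_day_dataset(n_individuals: int, n_days: int, steps_per_day: int = 2,
                     rng: np.random.Generator | None = None) -> TrackingDataset:
    """Small synthetic dataset with distinguishable per-day coordinates.

    Coordinates encode (individual, day, step) so that day relabelling is
    detectable: x = 100*ind + day, y = step + noise.
    """
    rng = rng or np.random.default_rng(0)
    rows = []
    for ind in range(n_individuals):
        for day in range(1, n_days + 1):
            for step in range(1, steps_per_day + 1):
                rows.append((ind, day, step,
                             100.0 * ind + day + rng.normal(0, 0.01),
                             float(step) + rng.normal(0, 0.01)))
    fixes = pd.DataFrame(rows, columns=["id", "day", "step", "x", "y"])
    return TrackingDataset(fixes)


@pytest.fixture
def tiny_config() -> SimConfig:
    return SimConfig(n_agents=3, n_days=2, steps_per_day=4, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
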