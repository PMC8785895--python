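import numpy as np
import pytest

from dmnage.io_core import TimeSeriesMatrix
from dmnage.synthetic_cohort import SimulationConfig, simulate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture()
def small_ts(rng):
    """120-volume, 6-ROI white-noise time series at TR = 2 s."""
    data = rng.standard_normal((120, 6))
    labels = tuple(f"ROI{i}" for i in range(6))
    return TimeSeriesMatrix("sub01", 2.0, data, labels)


@pytest.fixture(scope="session")
def tiny_cohort():
    """12-per-group simulated cohort shared across pipeline tests."""
    cfg = SimulationConfig(n_per_group=12, seed=11)
    records, series = simulate_cohort(cfg)
    return cfg, records, series
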