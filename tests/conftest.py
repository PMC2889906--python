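import numpy as np
import pytest

from galinduce.flow_sim import FlowParams
from galinduce.kinetics import KineticParams, TimeCourse, predict_mrna


@pytest.fixture(scope="session")
def hourly_grid():
    """The standard bulk-induction sampling grid: 2-h intervals over 14 h."""
    return np.arange(0.0, 14.1, 2.0)


@pytest.fixture(scope="session")
def wt_kinetics():
    """Wild-type-like kinetic truth in hours (onset 3.4 h)."""
    return KineticParams(onset_time=3.4, production_rate=0.3, degradation_rate=0.33)


@pytest.fixture(scope="session")
def wt_flow():
    """Wild-type-like single-cell truth: mean activation 4.2 h, rate 2.2/h."""
    return FlowParams(k_t=4.0, theta_t=1.05, k_x=4.0, theta_x=0.55, noise_mean=0.1, noise_var=0.0025)


@pytest.fixture()
def noiseless_timecourse(wt_kinetics, hourly_grid):
    clean = predict_mrna(wt_kinetics, hourly_grid)
    return TimeCourse(hourly_grid, np.tile(clean, (3, 1)), label="wt", time_unit="hours")
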