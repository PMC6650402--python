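import numpy as np
import pytest

from bioradiq import DEFAULT_CALIBRATION, F18
from bioradiq.quantify import ExposureSchedule
from bioradiq.simulate import scenario, simulate_stack


@pytest.fixture
def calib():
    return DEFAULT_CALIBRATION


@pytest.fixture
def f18():
    return F18


@pytest.fixture
def default_schedule():
    return ExposureSchedule.regular()


@pytest.fixture
def noiseless_sim():
    """One noiseless well per glucose condition: exact-recovery oracle."""
    phantom, design = scenario("fig3_glucose", seed=11, n_replicates=1, noise_scale=None, replicate_cv=0.0)
    return simulate_stack(phantom, design=design)


def fit_rates_frame(sim):
    """Fitted uptake rates merged with simulator ground truth."""
    from bioradiq.quantify import UptakeModel

    results = UptakeModel.from_stack(sim.stack, sim.roi_mask).fit()
    return results.to_frame().merge(sim.truth, on="roi_id")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
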