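import logging

import numpy as np
import pytest

from protgrn.datasets import STUDY_DAYS, SampleSheet
from protgrn.simulate import generate_truth, make_study_fixture, simulate_timeseries

logging.getLogger("protgrn").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def study_sheet() -> SampleSheet:
    """The study design: 11 days, two conditions, one sample per day."""
    return SampleSheet.two_condition(STUDY_DAYS)


@pytest.fixture(scope="session")
def toy_fixture():
    """20-protein ground truth plus a masked two-condition dataset."""
    return make_study_fixture("toy", seed=7)


@pytest.fixture(scope="session")
def small_truth():
    return generate_truth(10, edge_density=0.2, effect_fraction=0.25, seed=3)


@pytest.fixture(scope="session")
def clean_dataset(small_truth, study_sheet):
    """Complete (no missing values) simulated dataset on the study grid."""
    return simulate_timeseries(small_truth, study_sheet, obs_noise_sd=0.1, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
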