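import numpy as np
import pytest

from gatingnet.containers import EpochArray
from gatingnet.ddm import DDMParams
from gatingnet.synthetic import CohortSpec, gen_behavior


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects x 10 trials per cell, default (study-mean) DDM parameters."""
    return gen_behavior(CohortSpec(n_subjects=3, trials_per_condition=10, seed=7))


@pytest.fixture(scope="session")
def medium_cohort():
    """8 subjects with the study's switch/nonswitch parameter asymmetry."""
    return gen_behavior(CohortSpec(n_subjects=8, trials_per_condition=40, seed=11))


@pytest.fixture()
def sine_epochs():
    """Four identical 10 Hz trials on 3 channels, -2...2 s at 256 Hz."""
    sf = 256.0
    times = -2.0 + np.arange(1025) / sf
    x = np.sin(2 * np.pi * 10.0 * times)
    rng = np.random.default_rng(0)
    data = np.tile(x, (4, 3, 1)) + 0.01 * rng.standard_normal((4, 3, 1025))
    return EpochArray(data, times, sf, ["c0", "c1", "c2"])
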