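import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make the oracle module importable

from epgopt import PulseTrain, TissueParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def tissue():
    return TissueParams(t1=900.0, t2=80.0, tau=7.0)


@pytest.fixture
def tissue_norelax():
    return TissueParams(t1=900.0, t2=80.0, tau=7.0, relaxation_off=True)


def random_train(rng, n_pulses, max_alpha=np.pi):
    return PulseTrain(rng.uniform(0.05, max_alpha, n_pulses), rng.uniform(-np.pi, np.pi, n_pulses))


@pytest.fixture
def make_train(rng):
    return lambda n, max_alpha=np.pi: random_train(rng, n, max_alpha)
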