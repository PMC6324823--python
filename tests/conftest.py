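import numpy as np
import pytest

from cpsyn.minstim import TraceSpec
from cpsyn.synth import SynapseModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_model():
    return SynapseModel(
        n_synapses=5,
        silent_fraction=0.4,
        release_prob=0.3,
        quantal_mean_ampa_pA=10.0,
        quantal_cv=0.3,
        quantal_mean_nmda_pA=10.0,
        noise_sd_pA=1.0,
        seed=7,
    )


@pytest.fixture
def trace_spec():
    return TraceSpec()
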