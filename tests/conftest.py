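import numpy as np
import pytest
from hypothesis import settings

from telprop.params import ChiSpec, ModelAParams, ModelBParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def telegraph_a():
    """Unregulated one-stage telegraph model with moderate burst size."""
    return ModelAParams(kappa_f=0.5, kappa_b=1.0, lam=2.0)


@pytest.fixture
def telegraph_b():
    """Two-stage model with a 20-fold mRNA/protein decay separation."""
    return ModelBParams(kappa_0=1.0, kappa_1=1.0, lam=2.0, mu=1.0, eps=0.05)


@pytest.fixture
def chi_markov_spec():
    return ChiSpec(mode="markov")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
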