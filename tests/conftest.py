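import numpy as np
import pytest

from uwseg.nn import BatchNorm2d


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_trained_like(module, rng, gain=0.35):
    """Give a fresh network trained-network-like BN statistics.

    Running statistics near standardization and gains scaled for roughly
    unit-variance activation flow, so that inference-mode activations stay
    O(1) and fp32 equivalence checks are meaningful.
    """
    for m in module.modules():
        if isinstance(m, BatchNorm2d):
            m.running_mean[...] = rng.normal(0, 0.1, m.ch)
            m.running_var[...] = rng.uniform(0.8, 1.2, m.ch)
            m.weight.data[...] = rng.uniform(0.8, 1.2, m.ch) * gain
            m.bias.data[...] = rng.normal(0, 0.05, m.ch)
    return module


@pytest.fixture
def trained_like():
    return make_trained_like
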