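import numpy as np
import pytest

from eegaug.features import DEFeature, synthetic_layout
from eegaug.generative import GenerativeModel, NetworkSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_spec():
    """Smallest conv architecture: same layer pattern as the full model."""
    return NetworkSpec(kind="conv", in_shape=(5, 32, 32), latent_dim=8,
                       base_channels=4)


@pytest.fixture
def tiny_model(tiny_spec):
    return GenerativeModel(spec=tiny_spec, alpha=0.2, beta=0.1, seed=7)


@pytest.fixture
def map_batch(rng):
    """Random [0,1] image batch shaped like a stack of 5-band topomaps."""
    return rng.uniform(0.0, 1.0, (6, 5, 32, 32)).astype(np.float32)


@pytest.fixture(scope="session")
def layout62():
    return synthetic_layout(62)


@pytest.fixture(scope="session")
def channel_names62(layout62):
    return list(layout62.positions)


def constant_discriminator_score(model, bias: float) -> float:
    """Zero the final dense layers of both discriminators and set their bias,
    making D1 and D2 output the constant softplus(bias) for any input."""
    from eegaug._nn import Dense, softplus

    for net in (model.d1, model.d2):
        final = [l for l in net.layers if isinstance(l, Dense)][-1]
        final.params["W"][...] = 0.0
        final.params["b"][...] = bias
    return float(softplus(np.array(bias)))
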