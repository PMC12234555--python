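import numpy as np
import pytest

from tonguenet.model import GATongueNet, _preset


@pytest.fixture(scope="session")
def tiny_model() -> GATongueNet:
    """One shared tiny network in eval mode for shape/determinism tests."""
    model = GATongueNet(_preset("tiny"))
    model.eval()
    return model


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_mask_pair(rng, shape=(32, 32)):
    return (rng.integers(0, 2, shape).astype(np.uint8),
            rng.integers(0, 2, shape).astype(np.uint8))
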