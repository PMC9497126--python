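import numpy as np
import pytest

from sctforge.phantom import ArtifactParams, PhantomConfig, generate_pair


@pytest.fixture(scope="session")
def phantom_cfg():
    return PhantomConfig(image_size=128, n_cases=4, split=(2, 1, 1), seed=7)


@pytest.fixture(scope="session")
def head_pair(phantom_cfg):
    return generate_pair(phantom_cfg, 0)


@pytest.fixture(scope="session")
def head_image(head_pair):
    """A feature-rich clean head slice (HU ndarray)."""
    return head_pair.dct.values


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
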