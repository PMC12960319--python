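import numpy as np
import pytest

from mdrquant.phantom import PhantomParams, generate_phantom, generate_phantom_set
from mdrquant.segmentation import TrainConfig, train_segmenter


@pytest.fixture
def small_params():
    """A small but non-degenerate phantom geometry for fast unit tests."""
    return PhantomParams(width=64, height=80)


@pytest.fixture
def small_pair(small_params):
    return generate_phantom(small_params, seed=3)


@pytest.fixture(scope="session")
def tiny_segmenter():
    """A briefly trained thin U-Net shared by prediction/pipeline tests.

    Only rough quality is needed (contract tests plus nonempty gland and
    pectoral regions for the pipeline); ten epochs on 40 small phantoms
    takes ~10 s.
    """
    params = PhantomParams(width=80, height=96)
    ps = generate_phantom_set(44, params, seed=5, split=(40, 4))
    cfg = TrainConfig(epochs=10, depth=2, base_channels=8, batch_size=4,
                      learning_rate=1e-2, seed=0, target_size=(80, 96))
    seg, hist = train_segmenter(ps.subset("train").items, ps.subset("test").items, cfg)
    return seg


@pytest.fixture(scope="session")
def tiny_phantom_pair():
    """A phantom matching tiny_segmenter's input size."""
    return generate_phantom(PhantomParams(width=80, height=96), seed=21)
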