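import numpy as np
import pytest

from retinafd import synthetic as syn


@pytest.fixture(scope="session")
def default_tree_512():
    return syn.generate_vessel_tree(syn.TreeParams(seed=0), side=512)


@pytest.fixture(scope="session")
def default_phantom_512(default_tree_512):
    image, gt = syn.render_phantom(default_tree_512, side=512, seed=0)
    return image, gt


@pytest.fixture(scope="session")
def small_training_pairs():
    """Eight (image, mask) phantom pairs at side 64 for training smokes."""
    pairs = []
    for seed in range(8):
        tree = syn.generate_vessel_tree(
            syn.TreeParams(seed=seed, depth=5, initial_width=48), side=64)
        img, gt = syn.render_phantom(tree, side=64, seed=seed)
        pairs.append((img.pixels, gt))
    return pairs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
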