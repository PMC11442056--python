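import numpy as np
import pytest

from embryo3d.cee_features import load_default_specs
from embryo3d.segmentation import SegTrainConfig, train_segmenter
from embryo3d.synthetic_data import PhantomParams, generate_stack


@pytest.fixture(scope="session")
def specs():
    return load_default_specs()


def make_seg_pairs(n_stacks, image_px=128, seed0=100, quality_rng_seed=0):
    """(slice, mask) pairs from easy phantoms, for segmenter training/eval."""
    rng = np.random.default_rng(quality_rng_seed)
    pairs = []
    for s in range(n_stacks):
        params = PhantomParams(image_px=image_px, seed=seed0 + s)
        stack, masks = generate_stack(params, quality=float(rng.uniform()))
        for j in range(stack.n_slices):
            pairs.append((stack.slices[j], masks[j]))
    return pairs


@pytest.fixture(scope="session")
def seg_pairs():
    return make_seg_pairs(25)


@pytest.fixture(scope="session")
def trained_segmenter(seg_pairs):
    """Segmenter trained once per session on 200 easy phantom slices."""
    return train_segmenter(seg_pairs[:200], SegTrainConfig(epochs=10, seed=3))
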