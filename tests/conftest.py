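import numpy as np
import pytest

from nevuscope import SyntheticLesionSpec, generate_lesion_image


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def clean_lesion():
    """A zero-noise artifact-free elliptical lesion with ground truth."""
    spec = SyntheticLesionSpec(image_height=96, image_width=96,
                               semi_axes=(25.0, 16.0), rotation=0.4, seed=7)
    return generate_lesion_image(spec)


@pytest.fixture(scope="session")
def noisy_lesion():
    """A lesion with sensor noise and hair artifacts."""
    spec = SyntheticLesionSpec(image_height=96, image_width=96,
                               semi_axes=(25.0, 16.0), rotation=0.4,
                               noise_sd=15.0, n_hairs=3, seed=8)
    return generate_lesion_image(spec)


def random_mask(rng, shape=(20, 20), p=0.3):
    """A random non-empty binary mask."""
    while True:
        mask = (rng.random(shape) < p).astype(np.uint8)
        if mask.any():
            return mask
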