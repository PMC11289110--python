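import numpy as np
import pytest

from cystseg.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def five_cyst_scene():
    """A 256x256 scene with exactly five well-separated cysts."""
    return generate_scene(SceneConfig(width=256, height=256, n_cysts=5, seed=3))


@pytest.fixture(scope="session")
def three_cyst_scene():
    """The known-answer fixture scene: three cysts, generous canvas."""
    return generate_scene(SceneConfig(width=256, height=256, n_cysts=3, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240612)


def random_blob_mask(rng, shape=(64, 64), n_seeds=6, p_grow=0.6):
    """Random blobby mask: seeded points dilated by random amounts."""
    from scipy import ndimage

    mask = np.zeros(shape, dtype=bool)
    rr = rng.integers(0, shape[0], n_seeds)
    cc = rng.integers(0, shape[1], n_seeds)
    mask[rr, cc] = True
    n_iter = int(rng.integers(1, 6))
    mask = ndimage.binary_dilation(mask, iterations=n_iter)
    noise = rng.random(shape) < (1 - p_grow) * 0.05
    return mask ^ noise
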