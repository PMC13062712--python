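import numpy as np
import pytest

from seedpheno import CalibratedImage, SceneSpec, generate_scene
from seedpheno.pipeline import process_image


@pytest.fixture(scope="session")
def small_scene():
    """A 30-seed scene with some touching clusters and exact ground truth."""
    spec = SceneSpec(
        n_seeds=30, cluster_fraction=0.3, image_size=(512, 680), rng_seed=7
    )
    return generate_scene(spec)


@pytest.fixture(scope="session")
def small_scene_processed(small_scene):
    """(pre, masks, descriptors) for the small scene, computed once."""
    return process_image(small_scene.image)


@pytest.fixture(scope="session")
def examples300():
    """300 labeled examples produced by the full synthetic pipeline."""
    from seedpheno.pipeline import make_training_examples

    return make_training_examples(300, rng_seed=123, seeds_per_scene=150)


@pytest.fixture(scope="session")
def trained(examples300):
    from seedpheno import ForestConfig, train

    return train(examples300, ForestConfig())


@pytest.fixture(scope="session")
def trained_bundle(trained):
    return trained[0]


@pytest.fixture()
def disc_image():
    """A white field with one dark disc of radius 40 at the centre."""
    H, W = 256, 256
    yy, xx = np.mgrid[0:H, 0:W]
    mask = (yy - 128) ** 2 + (xx - 128) ** 2 <= 40**2
    px = np.full((H, W, 3), 255, dtype=np.uint8)
    px[mask] = (120, 90, 60)
    return CalibratedImage(pixels=px, source_id="disc"), mask


def make_disc_scene(centers, radius=12, grey=80, size=(256, 256)):
    """White image with dark discs at the given (x, y) centres."""
    H, W = size
    px = np.full((H, W, 3), 255, dtype=np.uint8)
    yy, xx = np.mgrid[0:H, 0:W]
    for cx, cy in centers:
        px[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = grey
    return CalibratedImage(pixels=px, source_id="discs")
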