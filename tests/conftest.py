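import numpy as np
import pytest

from fibrinet.image import ClotImage
from fibrinet.synth import SceneSpec, render_scene


@pytest.fixture(scope="session")
def default_scene():
    """One full-size synthetic network scene with ground truth."""
    return render_scene(SceneSpec(seed=11, n_branches=5, n_crossings=6))


@pytest.fixture(scope="session")
def sparse_noise_free_scene():
    """Few well-separated fibers, no noise: for diameter oracles."""
    spec = SceneSpec(
        seed=21,
        n_fibers=8,
        noise_sd_au=0.0,
        diameter_dist=("normal", 700.0, 150.0),
    )
    return render_scene(spec)


def make_flat_image(value=50.0, size=128, pixel_size_nm=57.6):
    return ClotImage(np.full((size, size), float(value)), pixel_size_nm=pixel_size_nm)
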