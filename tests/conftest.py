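import numpy as np
import pytest

from canopylai import (
    AcquisitionModel,
    GrayscaleImage,
    SceneSpec,
    generate_boolean_scene,
    render_acquisition,
)

QUIET = AcquisitionModel(noise_sd=0.0, blur_radius=0.0, vignetting_strength=0.0)


@pytest.fixture(scope="session")
def small_scene():
    """A 400x400 Boolean scene at 40% cover, shared across tests."""
    return generate_boolean_scene(
        SceneSpec(target_cover=0.40, circle_radius=8, width=400, height=400, seed=7)
    )


@pytest.fixture(scope="session")
def rendered_image(small_scene):
    """Default-model acquisition of the shared scene."""
    return GrayscaleImage(render_acquisition(small_scene, AcquisitionModel(seed=11)))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
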