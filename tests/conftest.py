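import numpy as np
import pytest

from dimerlabel import scene


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def centered_monomer_image():
    """Noiseless projection of a 13.2 A sphere centered in a 64x64 image."""
    spec = scene.SceneSpec(pixel_size=1.0, shape=(64, 64))
    truth = scene.ParticleTruth(id=0, kind="monomer", center=np.array([31.5, 31.5]))
    return scene.render_projection(truth, spec), spec, truth


@pytest.fixture
def dumbbell_image():
    """Noiseless 40 A dumbbell, in-plane axis, 96x96 image at 1 A/px."""
    spec = scene.SceneSpec(pixel_size=1.0, shape=(96, 96))
    truth = scene.ParticleTruth(
        id=0,
        kind="dimer",
        center=np.array([47.5, 47.5]),
        axis=np.array([0.0, 1.0]),
        separation=40.0,
    )
    return scene.render_projection(truth, spec), spec, truth
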