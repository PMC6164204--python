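import numpy as np
import pytest

from cytonuclei import (PipelineConfig, SceneConfig, degrade_image,
                        generate_scene, standard_degraded_fixture)
from cytonuclei.pipeline import preprocess_image


@pytest.fixture(scope="session")
def standard_scene():
    """The default synthetic scene: 256x256, 8 nuclei (2 abnormal), noise sigma 8."""
    return generate_scene(SceneConfig(seed=1))


@pytest.fixture(scope="session")
def preprocessed_scene(standard_scene):
    """Standard scene after the default preprocessing (median 3x3 + CLAHE)."""
    return preprocess_image(standard_scene.image, PipelineConfig())


@pytest.fixture(scope="session")
def clean_scene():
    """A noiseless scene, for contrast-direction and ground-truth checks."""
    return generate_scene(SceneConfig(seed=2, noise_sigma=0))


@pytest.fixture(scope="session")
def degraded_pair():
    """(clean, degraded) pair for filter/enhancer ranking."""
    return standard_degraded_fixture(seed=0)


@pytest.fixture(scope="session")
def artefact_scene(standard_scene):
    """Standard scene further degraded with speckle artefacts and noise."""
    degraded = degrade_image(standard_scene.image, noise_sigma=4,
                             n_artefacts=25, seed=9)
    return standard_scene, degraded


@pytest.fixture(scope="session")
def disk_fixture():
    """Piecewise-constant dark disk (value 70) on a bright field (220)."""
    rr, cc = np.mgrid[0:128, 0:128]
    disk = (rr - 64) ** 2 + (cc - 64) ** 2 <= 40 ** 2
    return np.where(disk, 70.0, 220.0), disk
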