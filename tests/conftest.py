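import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stretchquant import nuclei, synthetic

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def nuclei_scene():
    """10 intact + 3 fragment nuclei on a 256x256 frame, low noise."""
    specs = synthetic.random_nuclei_specs(10, 3, shape=(256, 256), seed=3)
    image, truth = synthetic.make_nuclei_image(
        specs, shape=(256, 256), noise_sd=0.01, seed=3
    )
    return specs, image, truth


@pytest.fixture(scope="session")
def somata_map():
    """Somatic ROI label map for movie fixtures (10 cells, no fragments)."""
    specs = synthetic.random_nuclei_specs(10, 0, shape=(128, 128), seed=9)
    labels = synthetic.paint_nuclei_labels(specs, (128, 128), seed=9)
    return nuclei.expand_to_soma(nuclei.LabelMap(labels), 6.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
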