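import numpy as np
import pytest

from berryspec.pipeline import SampleFeatures, synthesize_sample_features
from berryspec.synthetic import LatentQuality, generate_scene

DATASET_SEED = 7


@pytest.fixture(scope="session")
def dataset() -> SampleFeatures:
    """The default 120-fruit synthetic dataset, extracted once per session."""
    return synthesize_sample_features(n=120, groups=5, seed=DATASET_SEED)


@pytest.fixture(scope="session")
def scene():
    """One default-noise scene with mid-range quality latents."""
    return generate_scene(LatentQuality(6.0, 3.0, 0.65), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
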