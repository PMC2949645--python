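import numpy as np
import pytest

from ihcquant import AnalysisConfig, ImageScale, SyntheticSpec, generate_scene

#: Scale all synthetic test scenes are rendered at (px/um).
SCENE_SCALE = 2.2


@pytest.fixture(scope="session")
def scene_config() -> AnalysisConfig:
    """Analysis configuration matching the synthetic scene scale."""
    return AnalysisConfig(scale=ImageScale(SCENE_SCALE))


@pytest.fixture(scope="session")
def default_scene():
    """One mid-fraction noisy scene with its blankfield and ground truth."""
    spec = SyntheticSpec(dab_fraction=0.3, seed=42, noise_sd=3.0, vignette_strength=0.15)
    return generate_scene(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
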