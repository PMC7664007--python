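"""Shared fixtures: small synthetic scenes and a trained color model."""

import warnings

import numpy as np
import pytest

from ippkit import synthfield, weips

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def weedy_scene() -> synthfield.SyntheticScene:
    """Default study conditions, two plots, weeds and noise on."""
    return synthfield.generate_scene(synthfield.SceneParams(n_rows=1, n_cols=2, seed=11))


@pytest.fixture(scope="session")
def clean_scene() -> synthfield.SyntheticScene:
    """Noise-free, weed-free scene with a known 0.8 m / 0.4 m paraboloid dome."""
    return synthfield.generate_scene(
        synthfield.SceneParams(
            n_rows=1,
            n_cols=2,
            plant_height_range=(0.8, 0.8),
            plant_radius_range=(0.4, 0.4),
            weed_density_per_m2=0.0,
            dsm_noise_sd=0.0,
            color_noise_sd=0.0,
            seed=5,
        )
    )


@pytest.fixture(scope="session")
def color_model(weedy_scene) -> weips.ColorModel:
    return weips.train_color_model(weedy_scene.sample_labeled_pixels(200, seed=1), seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
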