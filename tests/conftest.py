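import numpy as np
import pytest

from canopyspec.pipeline import roi_library
from canopyspec.synth import (
    SceneConfig,
    default_component_models,
    generate_season,
)


@pytest.fixture(scope="session")
def grid():
    """The default sensor grid: 400-900 nm at 2.8 nm."""
    return np.arange(400.0, 900.0001, 2.8)


@pytest.fixture(scope="session")
def noise_free_models():
    """Default component models at heading with all noise switched off."""
    from dataclasses import replace

    models = default_component_models("HD")
    return {
        k: replace(m, pixel_noise_sd=0.0, amplitude_jitter_sd=0.0)
        for k, m in models.items()
    }


@pytest.fixture(scope="session")
def season():
    """A four-plot synthetic season (24 scenes, all four nitrogen rates)
    shared across tests."""
    cfg = SceneConfig(rows=50, cols=50, seed=42)
    return generate_season(cfg, n_plots=4)


@pytest.fixture(scope="session")
def season_library(season):
    scenes, _ = season
    return roi_library(scenes, n_per_class=40, seed=1)
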