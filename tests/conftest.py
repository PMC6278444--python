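import numpy as np
import pytest

import hsichem as h
from hsichem.pipeline import RunConfig, build_tables


@pytest.fixture(scope="session")
def axis():
    return np.linspace(975.0, 1646.0, 200)


@pytest.fixture(scope="session")
def signatures():
    return h.default_signatures()


@pytest.fixture(scope="session")
def noise_free_scene(signatures):
    """Zero-noise, zero-scatter scene: the generative model is invertible."""
    cfg = h.SceneConfig(seed=11, scatter_gain_sd=0.0, scatter_offset_sd=0.0, noise_sd=0.0)
    return cfg, h.generate_scene(cfg, signatures)


@pytest.fixture(scope="session")
def noisy_scene(signatures):
    cfg = h.SceneConfig(seed=5)
    return cfg, h.generate_scene(cfg, signatures)


@pytest.fixture(scope="session")
def mini_study():
    """Small but fully realistic study: 2 classes x 3 grades x 3 scenes at
    full spectral resolution, processed into pixel and object tables."""
    cfg = RunConfig.preset("desk", scenes_per_group=3)
    scenes = h.generate_study(
        scenes_per_group=cfg.scenes_per_group,
        base_config=cfg.scene_config(),
        master_seed=42,
    )
    pixels, objects = build_tables(scenes, cfg)
    return cfg, scenes, pixels, objects
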