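import numpy as np
import pytest

from sitmap import (GeometryParams, SceneConfig, TemplateValues, build_bank,
                    generate_dataset)


@pytest.fixture(scope="session")
def geom():
    return GeometryParams()


@pytest.fixture(scope="session")
def vals():
    return TemplateValues()


@pytest.fixture(scope="session")
def bank(geom, vals):
    return build_bank(geom, vals)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def clean_scene_cfg(angle=0.0, posture="upright", variation="normal", seed=0, **kw):
    """Noise-free, untranslated scene pinned at one rotation angle."""
    defaults = dict(rotation_range_deg=(angle, angle), translation_range_px=(0.0, 0.0),
                    weight_scale_range=(1.0, 1.0), noise_sd=0.0, spike_rate=0.0,
                    high_pressure_mode="hips", posture=posture, variation=variation,
                    seed=seed)
    defaults.update(kw)
    return SceneConfig(**defaults)


@pytest.fixture(scope="session")
def small_noisy_dataset():
    """Default-condition dataset: all postures/variations, sensor noise,
    mixed high-pressure mode, per-subject weights."""
    return generate_dataset(2, subjects=3, seed=42)
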