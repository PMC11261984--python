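import numpy as np
import pytest

from tomopick import PipelineConfig, PointPrompt, run_semantic
from tomopick.synthetic import (
    ParticleClass,
    SceneParams,
    generate_preset,
    generate_scene,
)


@pytest.fixture(scope="session")
def standard_scene():
    """The standard two-class scene used by the end-to-end checks."""
    return generate_preset("standard")


@pytest.fixture(scope="session")
def sphere_scene():
    """A single noiseless sphere of radius 8."""
    return generate_preset("sphere")


@pytest.fixture(scope="session")
def small_scene():
    """A compact noisy scene (3 small + 2 large particles) for pipeline
    tests that need speed more than statistics."""
    params = SceneParams(
        shape=(64, 64, 64),
        classes=(
            ParticleClass("A", 3, (6.0, 8.0), peak=3.0,
                          texture_freq=0.18, texture_amp=0.25),
            ParticleClass("B", 2, (10.0, 12.0), peak=3.0,
                          texture_freq=0.09, texture_amp=0.25,
                          texture_phase=1.0, texture_axis=(1, -1, 1)),
        ),
        noise_sigma=1.0,
        min_separation=22.0,
    )
    return generate_scene(params, seed=3)


def first_class_a_prompt(scene) -> PointPrompt:
    row = scene.particles[scene.particles["class"] == "A"].iloc[0]
    return PointPrompt(int(round(row.z)), int(round(row.y)), int(round(row.x)))


@pytest.fixture(scope="session")
def standard_semantic(standard_scene):
    """One full semantic run on the standard scene with default config,
    shared by the efficiency, picking-quality and pipeline tests."""
    cfg = PipelineConfig()
    result = run_semantic(standard_scene.tomogram,
                          [first_class_a_prompt(standard_scene)], cfg)
    return result, cfg
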