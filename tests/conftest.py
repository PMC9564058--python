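"""Shared fixtures: pre-simulated scenes reused across test modules."""

import pytest

from mastreg.pipeline import RunConfig, analyze_stack
from mastreg.scenegen import (
    NoiseConfig,
    ScenarioConfig,
    contact_scenario,
    simulate_scene,
)


@pytest.fixture(scope="session")
def pca_scene():
    """A noise-free anaphylaxis-arm contact video with ground truth."""
    cfg = contact_scenario(pca=True, seed=3, noise=NoiseConfig.off())
    stack, truth = simulate_scene(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def pca_analysis(pca_scene):
    cfg, stack, _ = pca_scene
    return analyze_stack(stack, RunConfig(scenario=cfg))


@pytest.fixture(scope="session")
def tiny_scene():
    """A small, quick two-channel scene for smoke tests."""
    cfg = ScenarioConfig(
        field_size_mm=(0.2, 0.2), n_frames=6, rng_seed=7, noise=NoiseConfig.off()
    )
    stack, truth = simulate_scene(cfg)
    return cfg, stack, truth
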