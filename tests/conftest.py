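"""Shared fixtures: synthetic scenes and trained combined-workflow models.

Scene rendering and classifier training are the slow parts of the suite, so
training scenes, held-out scenes, and the two-stage models are session-scoped
and shared between the unit and acceptance tests.  Held-out scene seeds are
disjoint from training seeds, so no training image re-enters evaluation.
"""

from __future__ import annotations

import numpy as np
import pytest

from organoscreen.pipeline import RunConfig
from organoscreen.synth import SceneSpec, render_scene
from organoscreen.training import train_models_from_scenes

TRAIN_SEEDS = range(200, 210)
HELD_OUT_SEEDS = range(300, 310)


@pytest.fixture(scope="session")
def combined_config() -> RunConfig:
    return RunConfig(mode="combined", min_area_px=50)


@pytest.fixture(scope="session")
def training_scenes():
    return [render_scene(SceneSpec(seed=s)) for s in TRAIN_SEEDS]


@pytest.fixture(scope="session")
def held_out_scenes():
    return [render_scene(SceneSpec(seed=s)) for s in HELD_OUT_SEEDS]


@pytest.fixture(scope="session")
def combined_models(training_scenes, combined_config):
    return train_models_from_scenes(training_scenes, config=combined_config, seed=7)


def sphere_scene(seed: int) -> SceneSpec:
    """A segmentation-recovery scene: 5-15 well-separated spheres, r >= 20 px."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 16))
    return SceneSpec(
        shape=(448, 448),
        n_organoid=0,
        n_big_sphere=n,
        n_small_sphere=0,
        n_cluster=0,
        n_debris=0,
        n_air_bubble=0,
        n_plate_edge=0,
        big_sphere_radius=(20, 36),
        noise_sigma=5.0,
        seed=seed,
    )
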