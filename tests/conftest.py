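import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from dyadkin.scene_io import MARKER_NAMES, AgentTrajectory, MarkerSet, Scene
from dyadkin.synthetic_scenes import generate_dataset, template_pose

DEFAULT_SEED = 0


def make_agent(coords: np.ndarray) -> AgentTrajectory:
    return AgentTrajectory(np.asarray(coords, dtype=float), MarkerSet())


def static_pose_coords(frames: int, openness: float = 0.6, offset=(0.0, 0.0, 0.0)) -> np.ndarray:
    pose = template_pose(openness) + np.asarray(offset)
    return np.repeat(pose[None, :, :], frames, axis=0)


def facing_pair(frames: int = 5, separation: float = 1000.0, openness: float = 0.6):
    """Two static agents facing each other along x, `separation` mm between
    their anatomical centroids."""
    mk = MarkerSet()
    anat = mk.indices(mk.anatomical_13)
    pose = template_pose(openness)
    cx = pose[anat].mean(axis=0)
    a1 = pose - cx
    a2 = a1.copy()
    # rotate agent 2 by 180 deg about z so it faces -x
    a2[:, 0] *= -1
    a2[:, 1] *= -1
    for l, r in mk.pairs:  # keep left/right labels anatomically correct
        li, ri = mk.index(l), mk.index(r)
        a2[[li, ri]] = a2[[ri, li]]
    a1 = a1.copy()
    a1[:, 0] -= separation / 2.0
    a2[:, 0] += separation / 2.0
    c1 = np.repeat(a1[None], frames, axis=0)
    c2 = np.repeat(a2[None], frames, axis=0)
    return c1, c2


def toy_scene(seed: int = 0, frames: int = 8, jitter: float = 30.0, separation: float = 900.0) -> Scene:
    """Small random scene for oracle comparisons: static pair + noise."""
    rng = np.random.default_rng(seed)
    c1, c2 = facing_pair(frames, separation)
    c1 = c1 + rng.normal(0.0, jitter, c1.shape)
    c2 = c2 + rng.normal(0.0, jitter, c2.shape)
    return Scene((make_agent(c1), make_agent(c2)), fps=100.0, emotion="happiness", scene_id=f"toy{seed}")


@pytest.fixture(scope="session")
def dataset48():
    """The default 48-scene synthetic stimulus set at the default seed."""
    return generate_dataset(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def features48(dataset48):
    from dyadkin.pipeline import features_table

    return features_table(dataset48)


@pytest.fixture(scope="session")
def small_dataset():
    """2 scenes per emotion, short clips would need config; keep defaults."""
    return generate_dataset(n_scenes_per_emotion=2, seed=3)
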