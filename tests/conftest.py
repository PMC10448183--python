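import numpy as np
import pytest

import facekin as fk
from facekin.geometry import load_face_template, project_points
from facekin.io import USED_POINTS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trajectory(coords, fps=10.0, image_size=(640, 480), participant_id="t0"):
    coords = np.asarray(coords, dtype=float)
    return fk.LandmarkTrajectory(
        participant_id=participant_id,
        fps=fps,
        frame_index=np.arange(len(coords)),
        coords=coords,
        image_size=image_size,
    )


@pytest.fixture
def template_face():
    """Neutral 51-point 2-D face: the 3-D template projected frontally."""
    tpl = load_face_template().loc[list(USED_POINTS)].to_numpy()
    uv = project_points(tpl, np.zeros(3), np.array([0.0, -96.0, 1792.0]), (640, 480))
    return uv  # (51, 2)


@pytest.fixture
def wiggly_trajectory(template_face, rng):
    """Short trajectory with smooth low-amplitude motion on every point."""
    n = 40
    t = np.arange(n)[:, None, None]
    drift = 2.0 * np.sin(2 * np.pi * t / 17.0) * rng.uniform(0.2, 1.0, (1, 51, 2))
    coords = template_face[None] + drift + rng.normal(0, 0.2, (n, 51, 2))
    return make_trajectory(coords)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny synthetic cohort shared by feature/model/pipeline tests."""
    spec = fk.CohortSpec(n_arms=7, n_controls=8, n_frames=300, seed=42)
    trajs, labels = fk.generate_cohort(spec)
    return spec, trajs, labels


@pytest.fixture(scope="session")
def small_table(small_cohort):
    _, trajs, labels = small_cohort
    return fk.build_feature_table(trajs, labels), labels
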