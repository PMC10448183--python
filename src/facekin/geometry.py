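"""Per-frame scalar signals derived from the 51-point landmark configuration.

Four families of signals are computed frame by frame:

* **EAR** — eye aspect ratio, the mean vertical eyelid distance over twice
  the horizontal eye width; drops toward zero during blinks.
* **MAR** — mouth aspect ratio, the analogous ratio on the inner-lip
  points 60..67; rises with mouth opening.
* **Head-pose Euler angles** — pitch/yaw/roll of a rigid head, recovered by
  fitting a canonical 3-D face template to the observed 2-D points under a
  pinhole camera (focal length = image width, principal point = image
  center) with a damped Gauss-Newton reprojection minimisation.
* **Nose-anchored angles** — the image-plane direction from the nose base
  (point 33) to every other used point.

All ratios are invariant under similarity transforms of the frame; the
angle series shift by exactly the rotation angle under in-plane rotation.
Degenerate frames yield NaN ("undefined value") rather than being dropped,
so every signal series has one entry per frame.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import numpy as np
import pandas as pd

from .io import LandmarkTrajectory, point_slot, USED_POINTS

#: template points used as 2-D/3-D correspondences for the pose fit
POSE_POINTS: tuple[int, ...] = (33, 27, 36, 45, 48, 54)

LEFT_EYE: tuple[int, ...] = (42, 43, 44, 45, 46, 47)
RIGHT_EYE: tuple[int, ...] = (36, 37, 38, 39, 40, 41)
INNER_MOUTH: tuple[int, ...] = (60, 61, 62, 63, 64, 65, 66, 67)

NOSE_ANCHOR = 33
#: targets of the nose-anchored angle series (all used points but the anchor)
ANGLE_TARGETS: tuple[int, ...] = tuple(i for i in USED_POINTS if i != NOSE_ANCHOR)


def load_face_template() -> pd.DataFrame:
    """Canonical neutral 3-D face template (mm-like units, y down, z toward
    the camera negative), indexed by iBUG point number 17..67."""
    with resources.files("facekin.data").joinpath("face_template_v1.csv").open() as fh:
        tpl = pd.read_csv(fh)
    return tpl.set_index("point").astype(float)


# ---------------------------------------------------------------------------
# aspect ratios
# ---------------------------------------------------------------------------


def _dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.linalg.norm(a - b, axis=-1)


def eye_aspect_ratio(eye_points: np.ndarray) -> np.ndarray:
    """EAR of one eye from its 6 ordered points p1..p6.

    ``eye_points`` has shape (..., 6, 2); p1/p4 are the horizontal corners,
    (p2, p6) and (p3, p5) the vertical pairs::

        EAR = (|p2 - p6| + |p3 - p5|) / (2 |p1 - p4|)

    A degenerate horizontal axis (|p1 - p4| = 0) yields NaN.
    """
    p = np.asarray(eye_points, dtype=float)
    width = _dist(p[..., 0, :], p[..., 3, :])
    vert = _dist(p[..., 1, :], p[..., 5, :]) + _dist(p[..., 2, :], p[..., 4, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(width > 0, vert / (2.0 * width), np.nan)
    return out[()] if out.ndim == 0 else out


def mouth_aspect_ratio(inner_mouth_points: np.ndarray) -> np.ndarray:
    """MAR from the 8 ordered inner-lip points 60..67.

    Defined by direct analogy to the EAR: the three vertical inner-lip
    distances over twice the corner distance::

        MAR = (|p61 - p67| + |p62 - p66| + |p63 - p65|) / (2 |p60 - p64|)
    """
    p = np.asarray(inner_mouth_points, dtype=float)
    width = _dist(p[..., 0, :], p[..., 4, :])
    vert = (
        _dist(p[..., 1, :], p[..., 7, :])
        + _dist(p[..., 2, :], p[..., 6, :])
        + _dist(p[..., 3, :], p[..., 5, :])
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(width > 0, vert / (2.0 * width), np.nan)
    return out[()] if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# head pose
# ---------------------------------------------------------------------------


def rotation_matrix(pitch: float, yaw: float, roll: float, degrees: bool = True) -> np.ndarray:
    """R = Rz(roll) @ Ry(yaw) @ Rx(pitch) on image-convention axes
    (x right, y down, z into the scene)."""
    if degrees:
        pitch, yaw, roll = np.deg2rad([pitch, yaw, roll])
    return _rotation_matrices(
        np.atleast_1d(pitch), np.atleast_1d(yaw), np.atleast_1d(roll)
    )[0]


def _rotation_matrices(pitch: np.ndarray, yaw: np.ndarray, roll: np.ndarray) -> np.ndarray:
    """Batched R = Rz(roll) Ry(yaw) Rx(pitch); angles in radians, shape (B,)."""
    cp, sp = np.cos(pitch), np.sin(pitch)
    cy, sy = np.cos(yaw), np.sin(yaw)
    cr, sr = np.cos(roll), np.sin(roll)
    R = np.empty(pitch.shape + (3, 3))
    R[..., 0, 0] = cr * cy
    R[..., 0, 1] = cr * sy * sp - sr * cp
    R[..., 0, 2] = cr * sy * cp + sr * sp
    R[..., 1, 0] = sr * cy
    R[..., 1, 1] = sr * sy * sp + cr * cp
    R[..., 1, 2] = sr * sy * cp - cr * sp
    R[..., 2, 0] = -sy
    R[..., 2, 1] = cy * sp
    R[..., 2, 2] = cy * cp
    return R


def project_points(
    points3d: np.ndarray,
    euler_deg: np.ndarray,
    translation: np.ndarray,
    image_size: tuple[int, int],
) -> np.ndarray:
    """Pinhole projection of template points under batched rigid poses.

    ``points3d`` (P, 3); ``euler_deg`` (..., 3) as (pitch, yaw, roll) in
    degrees; ``translation`` (..., 3).  Focal length = image width,
    principal point = image center.  Returns (..., P, 2) pixel coordinates.
    """
    w, h = image_size
    e = np.deg2rad(np.atleast_2d(euler_deg))
    t = np.atleast_2d(translation)
    R = _rotation_matrices(e[:, 0], e[:, 1], e[:, 2])
    cam = np.einsum("bij,pj->bpi", R, np.asarray(points3d, float)) + t[:, None, :]
    f = float(w)
    uv = np.empty(cam.shape[:-1] + (2,))
    uv[..., 0] = f * cam[..., 0] / cam[..., 2] + w / 2.0
    uv[..., 1] = f * cam[..., 1] / cam[..., 2] + h / 2.0
    if np.ndim(euler_deg) == 1:
        return uv[0]
    return uv


def _wrap_angle(deg: np.ndarray) -> np.ndarray:
    """Wrap to (-180, 180]."""
    return -((-np.asarray(deg) + 180.0) % 360.0 - 180.0)


def head_pose_angles(
    coords: np.ndarray,
    image_size: tuple[int, int],
    *,
    max_iter: int = 40,
    tol: float = 1e-10,
) -> np.ndarray:
    """Batched head-pose Euler angles from per-frame landmark coordinates.

    ``coords`` (n, 51, 2).  For every frame the six correspondence points
    (nose base 33, nose bridge 27, outer eye corners 36/45, mouth corners
    48/54) are fit to the canonical 3-D template under the pinhole camera
    by Levenberg-damped Gauss-Newton over (pitch, yaw, roll, tx, ty, tz).
    Returns (n, 3) degrees in (-180, 180]; frames where the fit fails are
    NaN.
    """
    coords = np.asarray(coords, dtype=float)
    tpl = load_face_template()
    P = tpl.loc[list(POSE_POINTS)].to_numpy()  # (6, 3)
    obs = coords[:, [point_slot(i) for i in POSE_POINTS], :]  # (n, 6, 2)
    n = len(obs)
    w, h = image_size
    f = float(w)

    # initialisation from the interocular distance and the centroid shift
    d_tpl = np.linalg.norm(P[POSE_POINTS.index(36)] - P[POSE_POINTS.index(45)])
    d_obs = np.linalg.norm(
        obs[:, POSE_POINTS.index(36)] - obs[:, POSE_POINTS.index(45)], axis=-1
    )
    with np.errstate(divide="ignore"):
        tz0 = np.where(d_obs > 0, f * d_tpl / d_obs, np.nan)
    mean_uv = obs.mean(axis=1)
    params = np.zeros((n, 6))
    params[:, 3] = (mean_uv[:, 0] - w / 2.0) * tz0 / f - P[:, 0].mean()
    params[:, 4] = (mean_uv[:, 1] - h / 2.0) * tz0 / f - P[:, 1].mean()
    params[:, 5] = tz0

    valid = np.all(np.isfinite(obs.reshape(n, -1)), axis=1) & np.isfinite(tz0)
    params[~valid] = np.nan

    def residuals(p: np.ndarray) -> np.ndarray:
        R = _rotation_matrices(p[:, 0], p[:, 1], p[:, 2])
        cam = np.einsum("bij,pj->bpi", R, P) + p[:, None, 3:6]
        z = cam[..., 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            u = f * cam[..., 0] / z + w / 2.0
            v = f * cam[..., 1] / z + h / 2.0
        return np.stack([u - obs[..., 0], v - obs[..., 1]], axis=-1).reshape(len(p), -1)

    lam = np.full(n, 1e-3)
    r = residuals(params)
    cost = np.einsum("bi,bi->b", r, r)
    scale = np.array([1e-4, 1e-4, 1e-4, 1e-2, 1e-2, 1e-2])  # finite-diff steps
    for _ in range(max_iter):
        J = np.empty((n, r.shape[1], 6))
        for k in range(6):
            dp = np.zeros(6)
            dp[k] = scale[k]
            J[:, :, k] = (residuals(params + dp) - r) / scale[k]
        JtJ = np.einsum("bik,bil->bkl", J, J)
        Jtr = np.einsum("bik,bi->bk", J, r)
        A = JtJ + lam[:, None, None] * np.eye(6)
        with np.errstate(all="ignore"):
            try:
                delta = np.linalg.solve(A, -Jtr[..., None])[..., 0]
            except np.linalg.LinAlgError:
                delta = np.full((n, 6), np.nan)
        cand = params + np.where(np.isfinite(delta), delta, 0.0)
        rc = residuals(cand)
        cost_c = np.einsum("bi,bi->b", rc, rc)
        improved = np.isfinite(cost_c) & (cost_c <= cost)
        settled = np.isfinite(cost_c) & (np.abs(cost - cost_c) <= tol * (cost + tol))
        params = np.where(improved[:, None], cand, params)
        r = np.where(improved[:, None], rc, r)
        lam = np.where(improved, lam * 0.3, lam * 5.0)
        cost = np.where(improved, cost_c, cost)
        if np.all(~valid | settled | (lam > 1e8)):
            break

    angles = _wrap_angle(np.rad2deg(params[:, :3]))
    # non-convergent fits: RMS reprojection error above 10% of eye distance
    rms = np.sqrt(cost / r.shape[1])
    bad = ~valid | ~np.isfinite(rms) | (rms > 0.10 * np.maximum(d_obs, 1.0))
    angles[bad] = np.nan
    return angles


def head_euler_angles(
    frame_landmarks: np.ndarray, image_size: tuple[int, int]
) -> tuple[float, float, float]:
    """(pitch, yaw, roll) in degrees for a single frame's (51, 2) landmarks."""
    ang = head_pose_angles(np.asarray(frame_landmarks, float)[None], image_size)[0]
    return float(ang[0]), float(ang[1]), float(ang[2])


# ---------------------------------------------------------------------------
# nose-anchored angles
# ---------------------------------------------------------------------------


def point_angle_series(
    trajectory: LandmarkTrajectory, target: int, anchor: int = NOSE_ANCHOR
) -> np.ndarray:
    """Per-frame image-plane angle (degrees) from anchor to target point.

    Image convention: 0° toward increasing x, positive toward increasing y
    (downward).  Frames with coincident points are NaN.
    """
    if anchor == target:
        raise ValueError("anchor and target must differ")
    a = trajectory.point_xy(anchor)
    b = trajectory.point_xy(target)
    d = b - a
    ang = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    ang[(d[:, 0] == 0) & (d[:, 1] == 0)] = np.nan
    return _wrap_angle(ang)


# ---------------------------------------------------------------------------
# per-frame signal bundle
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class FrameSignals:
    """Scalar signals of one frame (NaN = undefined value)."""

    ear: float
    mar: float
    euler: tuple[float, float, float]
    angle_33_to: dict[int, float]
    coords: np.ndarray  # (51, 2) raw pass-through


class FrameSignalSeries:
    """Struct-of-arrays view of per-frame signals for a whole trajectory.

    Behaves as a sequence of :class:`FrameSignals` (one per frame) while
    exposing the underlying arrays (``ear``, ``mar``, ``euler``,
    ``angles``, ``coords``) for vectorised summarisation.
    """

    def __init__(
        self,
        ear: np.ndarray,
        mar: np.ndarray,
        euler: np.ndarray,
        angles: np.ndarray,
        coords: np.ndarray,
        fps: float,
    ):
        self.ear = ear  # (n,)
        self.mar = mar  # (n,)
        self.euler = euler  # (n, 3) pitch, yaw, roll
        self.angles = angles  # (n, 50) ordered as ANGLE_TARGETS
        self.coords = coords  # (n, 51, 2)
        self.fps = fps

    def __len__(self) -> int:
        return len(self.ear)

    def __getitem__(self, t: int) -> FrameSignals:
        return FrameSignals(
            ear=float(self.ear[t]),
            mar=float(self.mar[t]),
            euler=tuple(self.euler[t]),
            angle_33_to={j: float(self.angles[t, k]) for k, j in enumerate(ANGLE_TARGETS)},
            coords=self.coords[t],
        )

    def angle_to(self, target: int) -> np.ndarray:
        return self.angles[:, ANGLE_TARGETS.index(target)]


def per_frame_signals(
    trajectory: LandmarkTrajectory, *, estimate_pose: bool = True
) -> FrameSignalSeries:
    """Compute EAR, MAR, head-pose Euler angles and nose-anchored angles.

    Per-frame EAR is the mean of the left-eye (42-47) and right-eye
    (36-41) aspect ratios.  Undefined values are recorded as NaN, never
    dropped, so all series share the trajectory's frame count.  Pose is
    skipped (all-NaN) when the image size is unknown or ``estimate_pose``
    is false.
    """
    c = trajectory.coords
    left = c[:, [point_slot(i) for i in LEFT_EYE], :]
    right = c[:, [point_slot(i) for i in RIGHT_EYE], :]
    ear = 0.5 * (eye_aspect_ratio(left) + eye_aspect_ratio(right))
    mar = mouth_aspect_ratio(c[:, [point_slot(i) for i in INNER_MOUTH], :])

    if estimate_pose and trajectory.image_size is not None:
        euler = head_pose_angles(c, trajectory.image_size)
    else:
        euler = np.full((trajectory.n_frames, 3), np.nan)

    anchor = c[:, point_slot(NOSE_ANCHOR), :]
    d = c[:, [point_slot(j) for j in ANGLE_TARGETS], :] - anchor[:, None, :]
    angles = np.degrees(np.arctan2(d[..., 1], d[..., 0]))
    angles[(d[..., 0] == 0) & (d[..., 1] == 0)] = np.nan
    angles = _wrap_angle(angles)

    return FrameSignalSeries(ear, mar, euler, angles, c, trajectory.fps)
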