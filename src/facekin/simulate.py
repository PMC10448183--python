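"""Synthetic two-group landmark-trajectory cohorts.

Emulates video-derived landmark recordings of an interview for two groups:
an at-risk (ARMS) group with blunted facial expressivity and a control
group, so every pipeline stage is testable without any recorded data.
A participant's trajectory is built from the canonical 3-D face template
deformed and moved by four ingredients:

* rigid head pose: three independent AR(1) Euler-angle processes (the
  ARMS group's variance scaled down by ``motion_sd_ratio``) plus a random
  constant orientation bias, projected through the same pinhole camera the
  analysis uses;
* expression events: smiles (mouth-corner displacement), brow raises and
  a continuous lower-lip "speech" oscillation, all amplitude-scaled by the
  participant's realised expressivity factor (group mean
  ``expressivity_attenuation`` for ARMS, 1 for controls, with lognormal
  between-participant heterogeneity);
* blinks: transient eyelid closures at the group's blink rate (not
  attenuated — blinking is largely involuntary);
* i.i.d. Gaussian pixel jitter standing in for landmark-localisation noise.

Synthetic SIPS negative-symptom items are drawn so that N2 (Avolition) and
N3 (Expression of Emotion) increase stochastically with a participant's
realised blunting, enabling convergent-validity testing.  Everything is
deterministic given the cohort seed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import _rotation_matrices, load_face_template
from .io import (
    ARMS,
    CONTROL,
    CohortLabels,
    LandmarkTrajectory,
    USED_POINTS,
    point_slot,
    write_labels_csv,
    write_landmark_csv,
)


@dataclasses.dataclass
class CohortSpec:
    """Parameters of a synthetic two-group cohort.

    Group sizes default to 58 ARMS / 70 controls; recordings default to
    3000 frames at 10 fps (a 5-minute interview).  The group effect is
    carried by ``expressivity_attenuation`` (ARMS expression amplitudes
    scaled by this factor) and ``motion_sd_ratio`` (ARMS head-motion SD
    ratio); setting both to 1 yields an exchangeable null cohort.
    """

    n_arms: int = 58
    n_controls: int = 70
    n_frames: int = 3000
    fps: float = 10.0
    image_size: tuple[int, int] = (640, 480)
    expressivity_attenuation: float = 0.6
    motion_sd_ratio: float = 0.7
    #: between-participant SD of log expressivity / log motion factors
    heterogeneity: float = 0.25
    blink_rate_arms: float = 15.0  # blinks / minute
    blink_rate_control: float = 15.0
    smile_rate: float = 2.0  # events / minute
    brow_rate: float = 3.0
    speech_amplitude: float = 2.0  # mm, continuous lower-lip oscillation
    jitter_sd: float = 0.5  # pixels
    head_motion_sd: tuple[float, float, float] = (2.5, 3.5, 1.5)  # pitch/yaw/roll deg
    ar1_phi: float = 0.95
    #: slope mapping blunting (1 - realised expressivity) to SIPS N2/N3
    sips_coupling: float = 6.0
    sips_noise_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_arms, self.n_controls) < 2:
            raise ValueError("need at least 2 participants per group")
        if not 0 < self.expressivity_attenuation <= 1:
            raise ValueError("expressivity_attenuation must lie in (0, 1]")
        if self.n_frames < 2 or self.fps <= 0:
            raise ValueError("need >= 2 frames and positive fps")
        if self.jitter_sd < 0 or self.motion_sd_ratio < 0:
            raise ValueError("spread parameters must be non-negative")


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) series with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - phi**2), size=n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        out[t] = phi * out[t - 1] + eps[t]
    return out


def _event_profile(n: int, onset: int, duration: int) -> np.ndarray:
    """Unit-amplitude raised-cosine event profile clipped to the recording."""
    prof = np.zeros(n)
    t = np.arange(duration)
    window = 0.5 * (1.0 - np.cos(2.0 * np.pi * (t + 1) / (duration + 1)))
    lo = max(onset, 0)
    hi = min(onset + duration, n)
    if hi > lo:
        prof[lo:hi] = window[lo - onset : hi - onset]
    return prof


def _add_events(
    rng: np.random.Generator,
    envelope: np.ndarray,
    rate_per_min: float,
    fps: float,
    mean_duration_s: float,
    amplitude: float,
) -> None:
    """Accumulate raised-cosine events into ``envelope`` in place."""
    n = len(envelope)
    minutes = n / fps / 60.0
    for _ in range(rng.poisson(rate_per_min * minutes)):
        onset = int(rng.integers(0, n))
        duration = max(2, int(round(rng.normal(mean_duration_s, 0.2 * mean_duration_s) * fps)))
        amp = amplitude * rng.lognormal(0.0, 0.3)
        envelope += amp * _event_profile(n, onset, duration)


# template deformation stencils: point -> (dx, dy, dz) per unit amplitude (mm)
_SMILE = {
    48: (-0.8, -0.6, 0.0), 54: (0.8, -0.6, 0.0),
    49: (-0.5, -0.4, 0.0), 53: (0.5, -0.4, 0.0),
    59: (-0.4, -0.3, 0.0), 55: (0.4, -0.3, 0.0),
    60: (-0.6, -0.4, 0.0), 64: (0.6, -0.4, 0.0),
    50: (-0.2, -0.2, 0.0), 52: (0.2, -0.2, 0.0),
}
_BROW = {i: (0.0, -1.0, 0.0) for i in range(17, 27)}
_BROW.update({37: (0.0, -0.25, 0.0), 38: (0.0, -0.25, 0.0),
              43: (0.0, -0.25, 0.0), 44: (0.0, -0.25, 0.0)})
# mouth opening: lower lip and jaw-side points move down
_MOUTH_OPEN = {
    55: (0.0, 0.6, 0.0), 56: (0.0, 0.9, 0.0), 57: (0.0, 1.0, 0.0),
    58: (0.0, 0.9, 0.0), 59: (0.0, 0.6, 0.0),
    65: (0.0, 0.9, 0.0), 66: (0.0, 1.0, 0.0), 67: (0.0, 0.9, 0.0),
    61: (0.0, -0.15, 0.0), 62: (0.0, -0.2, 0.0), 63: (0.0, -0.15, 0.0),
}
# blink: upper and lower eyelids meet halfway
_BLINK = {
    37: (0.0, 1.0, 0.0), 38: (0.0, 1.0, 0.0),
    40: (0.0, -1.0, 0.0), 41: (0.0, -1.0, 0.0),
    43: (0.0, 1.0, 0.0), 44: (0.0, 1.0, 0.0),
    46: (0.0, -1.0, 0.0), 47: (0.0, -1.0, 0.0),
}


def _stencil_matrix(stencil: dict[int, tuple[float, float, float]]) -> np.ndarray:
    m = np.zeros((len(USED_POINTS), 3))
    for point, d in stencil.items():
        m[point_slot(point)] = d
    return m


def _generate(
    group: str, spec: CohortSpec, participant_seed: int
) -> tuple[LandmarkTrajectory, float]:
    """Build one trajectory; returns it with the realised expressivity."""
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), int(participant_seed)])
    )
    n, fps = spec.n_frames, spec.fps
    is_arms = group == ARMS
    expr_base = spec.expressivity_attenuation if is_arms else 1.0
    motion_base = spec.motion_sd_ratio if is_arms else 1.0
    expr = expr_base * rng.lognormal(0.0, spec.heterogeneity)
    motion = motion_base * rng.lognormal(0.0, spec.heterogeneity * 0.6)
    blink_rate = spec.blink_rate_arms if is_arms else spec.blink_rate_control

    # head pose: AR(1) around a per-participant orientation bias
    euler = np.empty((n, 3))
    for k, sd in enumerate(spec.head_motion_sd):
        bias = rng.normal(0.0, 2.0)
        euler[:, k] = bias + _ar1(rng, n, sd * motion, spec.ar1_phi)

    # expression envelopes (mm amplitudes)
    smile = np.zeros(n)
    _add_events(rng, smile, spec.smile_rate, fps, 1.5, 6.0 * expr)
    brow = np.zeros(n)
    _add_events(rng, brow, spec.brow_rate, fps, 1.0, 4.0 * expr)
    if spec.speech_amplitude > 0:
        speech = np.abs(_ar1(rng, n, 1.2, 0.8)) * spec.speech_amplitude * expr
    else:
        speech = np.zeros(n)
    blink = np.zeros(n)
    if blink_rate > 0:
        _add_events(rng, blink, blink_rate, fps, 0.3, 4.5)
    np.clip(blink, 0.0, 4.9, out=blink)  # lids never cross

    tpl = load_face_template().loc[list(USED_POINTS)].to_numpy()  # (51, 3)
    deform = (
        smile[:, None, None] * _stencil_matrix(_SMILE)[None]
        + brow[:, None, None] * _stencil_matrix(_BROW)[None]
        + speech[:, None, None] * _stencil_matrix(_MOUTH_OPEN)[None]
        + blink[:, None, None] * _stencil_matrix(_BLINK)[None]
    )
    points = tpl[None] + deform  # (n, 51, 3)

    R = _rotation_matrices(*np.deg2rad(euler).T)  # (n, 3, 3)
    w, h = spec.image_size
    f = float(w)
    t = np.array([0.0, -0.15 * f, 2.8 * f])  # face roughly centred in frame
    cam = np.einsum("bij,bpj->bpi", R, points) + t
    uv = np.empty((n, len(USED_POINTS), 2))
    uv[..., 0] = f * cam[..., 0] / cam[..., 2] + w / 2.0
    uv[..., 1] = f * cam[..., 1] / cam[..., 2] + h / 2.0
    if spec.jitter_sd > 0:
        uv += rng.normal(0.0, spec.jitter_sd, size=uv.shape)

    traj = LandmarkTrajectory(
        participant_id=f"p{participant_seed:04d}",
        fps=fps,
        frame_index=np.arange(n),
        coords=uv,
        image_size=spec.image_size,
    )
    return traj, expr


def generate_trajectory(
    group: str, spec: CohortSpec, participant_seed: int
) -> LandmarkTrajectory:
    """One synthetic participant's landmark trajectory (deterministic)."""
    if group not in (ARMS, CONTROL):
        raise ValueError(f"unknown group '{group}'")
    return _generate(group, spec, participant_seed)[0]


def _sips_items(
    rng: np.random.Generator, expr: float, is_arms: bool, spec: CohortSpec
) -> dict[str, int]:
    """Integer SIPS negative items; N2/N3 track realised blunting."""
    blunting = max(0.0, 1.0 - expr)
    items: dict[str, int] = {}
    for item in ("N2", "N3"):
        latent = spec.sips_coupling * blunting + rng.normal(0.0, spec.sips_noise_sd)
        items[item] = int(np.clip(round(latent), 0, 6))
    for item in ("N1", "N4", "N5", "N6"):
        base = 1.5 if is_arms else 0.3
        items[item] = int(np.clip(round(base + rng.normal(0.0, 1.0)), 0, 6))
    return items


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[LandmarkTrajectory], CohortLabels]:
    """Full two-group cohort with labels and synthetic SIPS items."""
    trajectories: list[LandmarkTrajectory] = []
    rows = []
    k = 0
    for group, count, prefix in (
        (ARMS, spec.n_arms, "arms"),
        (CONTROL, spec.n_controls, "ctrl"),
    ):
        for j in range(count):
            traj, expr = _generate(group, spec, k)
            traj.participant_id = f"{prefix}_{j:03d}"
            trajectories.append(traj)
            rng = np.random.default_rng(
                np.random.SeedSequence([int(spec.seed), int(k), 7])
            )
            row = {"participant_id": traj.participant_id, "group": group}
            row.update(_sips_items(rng, expr, group == ARMS, spec))
            row["age"] = int(np.clip(round(rng.normal(23.0, 4.0)), 16, 35))
            row["gender"] = "F" if rng.random() < 0.5 else "M"
            row["education"] = int(np.clip(round(rng.normal(12.0, 2.5)), 6, 20))
            row["expressivity"] = expr
            rows.append(row)
            k += 1
    labels = CohortLabels(pd.DataFrame(rows).set_index("participant_id"))
    return trajectories, labels


def write_cohort(
    spec: CohortSpec, out_dir: str | Path
) -> tuple[list[Path], Path]:
    """Materialise a cohort as per-participant landmark CSVs + labels CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trajectories, labels = generate_cohort(spec)
    paths = [
        write_landmark_csv(t, out_dir / f"{t.participant_id}.csv")
        for t in trajectories
    ]
    labels_path = write_labels_csv(labels, out_dir / "labels.csv")
    return paths, labels_path
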