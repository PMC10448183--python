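"""Reading, validating and writing facial-landmark trajectory files.

The pipeline starts from precomputed per-frame landmark coordinates: 51 of
the 68 iBUG/300-W points (indices 17..67; the jawline 0..16 is excluded),
stored one row per frame in a wide CSV dialect::

    frame, x_17, ..., x_67, y_17, ..., y_67

Coordinates follow the image convention: origin top-left, y axis pointing
downward, units of pixels.  Cohort label files carry the group assignment
(ARMS vs CONTROL) and optional SIPS negative-symptom item scores.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: landmark indices used throughout the package (iBUG 68-point numbering,
#: jawline excluded)
USED_POINTS: tuple[int, ...] = tuple(range(17, 68))
N_POINTS = len(USED_POINTS)  # 51

ARMS = "ARMS"
CONTROL = "CONTROL"
GROUPS = (ARMS, CONTROL)

SIPS_ITEMS = ("N1", "N2", "N3", "N4", "N5", "N6")


class LandmarkFormatError(ValueError):
    """A landmark/label file does not follow the expected dialect."""


class LandmarkParseError(ValueError):
    """A cell in a landmark file could not be parsed as a number."""


class IntegrityError(ValueError):
    """Structural inconsistency (duplicate frames, duplicate participants...)."""


def point_slot(point: int) -> int:
    """Array position of an iBUG point index within the 51-point layout."""
    if not 17 <= point <= 67:
        raise ValueError(f"point index {point} outside the used range 17..67")
    return point - 17


@dataclasses.dataclass
class LandmarkTrajectory:
    """One participant's per-frame 51-point landmark coordinates.

    Attributes
    ----------
    participant_id : str
        Cohort-unique identifier.
    fps : float
        Recording frame rate (frames/second, > 0).
    frame_index : (n,) int array
        Strictly increasing frame numbers (gaps allowed, see
        :func:`interpolate_gaps`).
    coords : (n, 51, 2) float array
        Pixel coordinates, ``coords[t, point_slot(i)] == (x_i, y_i)`` at
        frame ``t``; y grows downward.
    image_size : (width, height) or None
        Source frame size in pixels; required for head-pose estimation.
    breaks : tuple of (int, int)
        Recorded gaps ``(last_frame_before, first_frame_after)`` that were
        deliberately left unfilled by :func:`interpolate_gaps`.
    """

    participant_id: str
    fps: float
    frame_index: np.ndarray
    coords: np.ndarray
    image_size: tuple[int, int] | None = None
    breaks: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.fps <= 0:
            raise IntegrityError("fps must be positive")
        if self.frame_index.ndim != 1 or len(self.frame_index) < 2:
            raise IntegrityError("a trajectory needs at least 2 frames")
        if self.coords.shape != (len(self.frame_index), N_POINTS, 2):
            raise IntegrityError(
                f"coords shape {self.coords.shape} does not match "
                f"({len(self.frame_index)}, {N_POINTS}, 2)"
            )
        diffs = np.diff(self.frame_index)
        if np.any(diffs <= 0):
            raise IntegrityError("frame indices must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise IntegrityError("all landmark coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)

    def point_xy(self, point: int) -> np.ndarray:
        """(n, 2) coordinate series of one landmark point."""
        return self.coords[:, point_slot(point), :]

    def __eq__(self, other: object) -> bool:  # value semantics for tests
        if not isinstance(other, LandmarkTrajectory):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.fps == other.fps
            and self.image_size == other.image_size
            and np.array_equal(self.frame_index, other.frame_index)
            and np.array_equal(self.coords, other.coords)
        )


def _coordinate_columns() -> list[str]:
    return [f"x_{i}" for i in USED_POINTS] + [f"y_{i}" for i in USED_POINTS]


def read_landmark_csv(
    path: str | Path,
    *,
    fps: float = 10.0,
    participant_id: str | None = None,
    image_size: tuple[int, int] | None = None,
) -> LandmarkTrajectory:
    """Read one participant's landmark trajectory from a wide CSV file.

    Raises
    ------
    LandmarkFormatError
        If a required column (``frame`` or any of ``x_17..x_67`` /
        ``y_17..y_67``) is absent; the message names the missing column.
    LandmarkParseError
        If a cell is not numeric; the message carries the 1-based data row.
    IntegrityError
        On duplicate frame indices or violated trajectory invariants.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    needed = ["frame"] + _coordinate_columns()
    for col in needed:
        if col not in frame.columns:
            raise LandmarkFormatError(f"{path.name}: missing required column '{col}'")
    numeric = frame[needed].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame[needed].notna()
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        raise LandmarkParseError(
            f"{path.name}: non-numeric value in column '{needed[col]}', data row {row + 1}"
        )
    if numeric.isna().to_numpy().any():
        row, col = np.argwhere(numeric.isna().to_numpy())[0]
        raise LandmarkParseError(
            f"{path.name}: empty cell in column '{needed[col]}', data row {row + 1}"
        )
    idx = numeric["frame"].to_numpy()
    if len(np.unique(idx)) != len(idx):
        dup = int(idx[pd.Index(idx).duplicated()][0])
        raise IntegrityError(f"{path.name}: duplicate frame index {dup}")
    order = np.argsort(idx)
    n = len(idx)
    # re-parse through numpy's correctly-rounded strtod so a write/read
    # round trip is bit exact (pandas' fast parser can be 1 ulp off)
    coords = np.empty((n, N_POINTS, 2))
    coords[:, :, 0] = frame[[f"x_{i}" for i in USED_POINTS]].to_numpy(dtype=np.float64)[order]
    coords[:, :, 1] = frame[[f"y_{i}" for i in USED_POINTS]].to_numpy(dtype=np.float64)[order]
    return LandmarkTrajectory(
        participant_id=participant_id or path.stem,
        fps=fps,
        frame_index=idx[order].astype(np.int64),
        coords=coords,
        image_size=image_size,
    )


def write_landmark_csv(trajectory: LandmarkTrajectory, path: str | Path) -> Path:
    """Write a trajectory in the wide CSV dialect (103 columns).

    Values are written at full double precision so a read/write round trip
    is bit exact.
    """
    trajectory.validate()
    path = Path(path)
    data = {"frame": trajectory.frame_index}
    for k, i in enumerate(USED_POINTS):
        data[f"x_{i}"] = trajectory.coords[:, k, 0]
    for k, i in enumerate(USED_POINTS):
        data[f"y_{i}"] = trajectory.coords[:, k, 1]
    pd.DataFrame(data).to_csv(path, index=False)  # shortest-repr floats: exact
    return path


def interpolate_gaps(
    trajectory: LandmarkTrajectory, max_gap: int = 5
) -> LandmarkTrajectory:
    """Fill short frame-index gaps by per-coordinate linear interpolation.

    Gaps of at most ``max_gap`` missing frames are filled; longer gaps are
    left untouched and recorded in ``breaks`` (no fabrication of long
    spans).  Observed frames are never altered, so the operation is
    idempotent.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    idx = trajectory.frame_index
    gaps = np.diff(idx) - 1
    if not np.any(gaps > 0):
        return trajectory
    new_frames: list[np.ndarray] = []
    new_coords: list[np.ndarray] = []
    breaks = list(trajectory.breaks)
    for t in range(len(idx) - 1):
        new_frames.append(idx[t : t + 1])
        new_coords.append(trajectory.coords[t : t + 1])
        g = int(gaps[t])
        if g == 0:
            continue
        if g <= max_gap:
            missing = np.arange(idx[t] + 1, idx[t + 1])
            w = (missing - idx[t]) / (idx[t + 1] - idx[t])
            left = trajectory.coords[t]
            right = trajectory.coords[t + 1]
            filled = left[None] + w[:, None, None] * (right - left)[None]
            new_frames.append(missing)
            new_coords.append(filled)
        else:
            brk = (int(idx[t]), int(idx[t + 1]))
            if brk not in breaks:
                breaks.append(brk)
    new_frames.append(idx[-1:])
    new_coords.append(trajectory.coords[-1:])
    return LandmarkTrajectory(
        participant_id=trajectory.participant_id,
        fps=trajectory.fps,
        frame_index=np.concatenate(new_frames),
        coords=np.concatenate(new_coords, axis=0),
        image_size=trajectory.image_size,
        breaks=tuple(breaks),
    )


# ---------------------------------------------------------------------------
# cohort labels
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CohortLabels:
    """Group membership and optional SIPS item scores for a cohort.

    ``table`` is indexed by participant_id with a ``group`` column in
    {ARMS, CONTROL}; optional integer columns N1..N6 hold SIPS negative
    item scores (0-6, NaN = missing) and optional covariates age, gender,
    education are passed through untouched.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise IntegrityError(f"duplicate participant id '{dup}'")
        if "group" not in self.table.columns:
            raise LandmarkFormatError("labels: missing required column 'group'")
        bad = ~self.table["group"].isin(GROUPS)
        if bad.any():
            raise LandmarkFormatError(
                f"labels: unknown group value '{self.table['group'][bad].iloc[0]}'"
            )
        for item in SIPS_ITEMS:
            if item in self.table.columns:
                vals = self.table[item].dropna()
                if len(vals) and ((vals < 0) | (vals > 6)).any():
                    raise ValueError(f"labels: {item} scores must lie in [0, 6]")

    @property
    def participant_ids(self) -> list[str]:
        return list(self.table.index)

    def group_of(self, participant_id: str) -> str:
        return str(self.table.loc[participant_id, "group"])

    def groups(self, ids: Sequence[str] | None = None) -> np.ndarray:
        ids = list(ids) if ids is not None else self.participant_ids
        return self.table.loc[ids, "group"].to_numpy()

    def sips_item(self, item: str, ids: Sequence[str] | None = None) -> np.ndarray:
        if item not in self.table.columns:
            raise KeyError(f"labels carry no SIPS item '{item}'")
        ids = list(ids) if ids is not None else self.participant_ids
        return self.table.loc[ids, item].to_numpy(dtype=float)


def read_labels_csv(path: str | Path) -> CohortLabels:
    """Read a cohort label file (participant_id, group, N1..N6, covariates)."""
    frame = pd.read_csv(path)
    if "participant_id" not in frame.columns:
        raise LandmarkFormatError("labels: missing required column 'participant_id'")
    frame["participant_id"] = frame["participant_id"].astype(str)
    return CohortLabels(frame.set_index("participant_id"))


def write_labels_csv(labels: CohortLabels, path: str | Path) -> Path:
    path = Path(path)
    labels.table.rename_axis("participant_id").reset_index().to_csv(path, index=False)
    return path
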