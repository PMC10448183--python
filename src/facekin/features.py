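"""Per-participant summary features of the landmark-signal time series.

Because recordings differ in length, each per-frame signal is collapsed
into robust summary statistics — interquartile range (IQR), median absolute
deviation (MAD), Tukey-fence outlier fraction, lag-1 partial
autocorrelation — plus Spearman correlations between bilaterally symmetric
landmark pairs and below-first-quartile occupancy of the aspect ratios.

The default inventory contains exactly 649 named features:

====== ============================================================== =====
group  contents                                                       count
====== ============================================================== =====
G1     coordinates, 51 points x 2 axes x {IQR, MAD, outliers, PACF1}    408
G2     nose-anchored angles 33->j x {IQR, MAD, outliers}                150
G3     Spearman rho of 21 symmetric point pairs x 2 axes                 42
G4     Euler angles x {IQR, MAD, outliers}                                9
G5     EAR x {IQR, MAD, outliers, PACF1, below-Q1 %}                      5
G6     MAR x {IQR, MAD, outliers, PACF1, below-Q1 %}                      5
G7     inter-frame speed MAD, 30 expressive points                       30
====== ============================================================== =====

The manifest is a plain data object (and a versioned CSV fixture), so an
alternative inventory can be swapped in without code changes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.tsa.stattools import levinson_durbin as _levinson_durbin

from .geometry import ANGLE_TARGETS, FrameSignalSeries, per_frame_signals
from .io import CohortLabels, IntegrityError, LandmarkTrajectory, USED_POINTS, point_slot

# statistic codes used in manifests
IQR = "IQR"
MAD = "MAD"
OUTLIER_FRACTION = "OUTLIER_FRACTION"
PACF1 = "PACF1"
SPEARMAN = "SPEARMAN"
BELOW_Q1_PCT = "BELOW_Q1_PCT"
SPEED_MAD = "SPEED_MAD"

#: bilaterally symmetric landmark pairs (left/right mirror indices)
SYMMETRIC_PAIRS: tuple[tuple[int, int], ...] = (
    # eyebrows
    (17, 26), (18, 25), (19, 24), (20, 23), (21, 22),
    # eyes
    (36, 45), (37, 44), (38, 43), (39, 42), (40, 47), (41, 46),
    # nose
    (31, 35), (32, 34),
    # outer mouth
    (48, 54), (49, 53), (50, 52), (59, 55), (58, 56),
    # inner mouth
    (60, 64), (61, 63), (67, 65),
)

#: expressive subset used for the inter-frame speed features
SPEED_POINTS: tuple[int, ...] = tuple(range(36, 48)) + tuple(range(48, 60)) + tuple(
    range(19, 25)
)


# ---------------------------------------------------------------------------
# scalar summary statistics
# ---------------------------------------------------------------------------


def _clean(series: np.ndarray) -> np.ndarray:
    x = np.asarray(series, dtype=float).ravel()
    return x[np.isfinite(x)]


def robust_dispersion(series: np.ndarray) -> tuple[float, float]:
    """(IQR, MAD) of a series, ignoring missing values.

    IQR uses linear-interpolation (type-7) quantiles; MAD is the unscaled
    median absolute deviation from the median.  Fewer than 2 observed
    values yields (nan, nan).
    """
    x = _clean(series)
    if len(x) < 2:
        return (np.nan, np.nan)
    q1, q3 = np.percentile(x, [25, 75])
    mad = float(np.median(np.abs(x - np.median(x))))
    return (float(q3 - q1), mad)


def outlier_fraction(series: np.ndarray) -> float:
    """Fraction of values outside the Tukey fences [Q1-1.5 IQR, Q3+1.5 IQR]."""
    x = _clean(series)
    if len(x) < 4:
        return np.nan
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return float(np.mean((x < lo) | (x > hi)))


def pacf_coefficient(series: np.ndarray, lag: int = 1) -> float:
    """Partial autocorrelation at ``lag`` via Levinson-Durbin recursion on
    the (biased) sample autocorrelations.  Zero-variance or too-short
    series yield nan."""
    if lag < 1:
        raise ValueError("lag must be a positive integer")
    x = _clean(series)
    if len(x) <= lag + 1 or np.ptp(x) == 0:
        return np.nan
    # biased sample autocovariances up to `lag`, then the Levinson-Durbin
    # recursion (same estimator as statsmodels pacf(method='ldb'), but
    # without forming the full O(n^2) autocovariance sequence)
    d = x - x.mean()
    acov = np.array([d[: len(d) - k] @ d[k:] for k in range(lag + 1)]) / len(d)
    _, _, pacf_vals, _, _ = _levinson_durbin(acov, nlags=lag, isacov=True)
    return float(pacf_vals[lag])


def spearman_pair(series_a: np.ndarray, series_b: np.ndarray) -> float:
    """Spearman rho of two equally long series (average ranks for ties),
    on pairwise-complete observations.  Needs >= 3 complete pairs and
    non-degenerate ranks in both."""
    a = np.asarray(series_a, dtype=float).ravel()
    b = np.asarray(series_b, dtype=float).ravel()
    if len(a) != len(b):
        raise ValueError("series must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if len(a) < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    return float(sps.spearmanr(a, b).statistic)


def below_reference_fraction(series: np.ndarray, reference: float) -> float:
    """Percentage (0-100) of observed values strictly below ``reference``."""
    if not np.isfinite(reference):
        raise ValueError("reference must be finite")
    x = _clean(series)
    if len(x) == 0:
        return np.nan
    return float(100.0 * np.mean(x < reference))


# ---------------------------------------------------------------------------
# feature manifest
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    source: str  # per-frame signal the statistic is computed on
    statistic: str


@dataclasses.dataclass
class FeatureManifest:
    """Ordered, named inventory of summary features."""

    entries: tuple[FeatureDescriptor, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise IntegrityError("feature names in a manifest must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.name, e.source, e.statistic) for e in self.entries],
            columns=["name", "source", "statistic"],
        )

    def save_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureManifest":
        return cls(
            tuple(
                FeatureDescriptor(str(r.name), str(r.source), str(r.statistic))
                for r in frame.itertuples(index=False)
            )
        )

    @classmethod
    def load_csv(cls, path: str | Path) -> "FeatureManifest":
        return cls.from_frame(pd.read_csv(path))


def default_manifest() -> FeatureManifest:
    """The default 649-feature inventory (groups G1-G7 above)."""
    entries: list[FeatureDescriptor] = []
    stat_suffix = {IQR: "iqr", MAD: "mad", OUTLIER_FRACTION: "outliers", PACF1: "pacf"}
    # G1: per-coordinate robust summaries
    for i in USED_POINTS:
        for axis in ("x", "y"):
            src = f"face_{i}_{axis}"
            for stat in (IQR, MAD, OUTLIER_FRACTION, PACF1):
                entries.append(FeatureDescriptor(f"{src}_{stat_suffix[stat]}", src, stat))
    # G2: nose-anchored angle summaries
    for j in ANGLE_TARGETS:
        src = f"angle_33_{j}"
        for stat in (IQR, MAD, OUTLIER_FRACTION):
            entries.append(
                FeatureDescriptor(f"face_33_angle_face{j}_{stat_suffix[stat]}", src, stat)
            )
    # G3: symmetric-pair Spearman correlations
    for i, j in SYMMETRIC_PAIRS:
        for axis in ("x", "y"):
            entries.append(
                FeatureDescriptor(
                    f"spearman_{i}_{j}_{axis}", f"pair_{i}_{j}_{axis}", SPEARMAN
                )
            )
    # G4: Euler-angle summaries
    for name in ("pitch", "yaw", "roll"):
        src = f"euler_{name}"
        for stat in (IQR, MAD, OUTLIER_FRACTION):
            entries.append(FeatureDescriptor(f"{src}_{stat_suffix[stat]}", src, stat))
    # G5/G6: aspect-ratio summaries
    for src in ("ear", "mar"):
        for stat in (IQR, MAD, OUTLIER_FRACTION, PACF1):
            entries.append(FeatureDescriptor(f"{src}_{stat_suffix[stat]}", src, stat))
        entries.append(FeatureDescriptor(f"{src}_below_q1_pct", src, BELOW_Q1_PCT))
    # G7: inter-frame speed MAD on the expressive subset
    for i in SPEED_POINTS:
        entries.append(FeatureDescriptor(f"face_{i}_speed_mad", f"speed_{i}", SPEED_MAD))
    return FeatureManifest(tuple(entries))


# ---------------------------------------------------------------------------
# per-participant feature vector
# ---------------------------------------------------------------------------


def unwrap_degrees(series: np.ndarray) -> np.ndarray:
    """Unwrap an angular series (degrees) across the +/-180 boundary,
    skipping missing values, so dispersion summaries are not inflated by
    wrap-around jumps."""
    x = np.asarray(series, dtype=float).copy()
    mask = np.isfinite(x)
    if mask.sum() >= 2:
        x[mask] = np.unwrap(x[mask], period=360.0)
    return x


def _source_series(signals: FrameSignalSeries, source: str) -> np.ndarray:
    if source == "ear":
        return signals.ear
    if source == "mar":
        return signals.mar
    if source.startswith("euler_"):
        return signals.euler[:, ("pitch", "yaw", "roll").index(source[6:])]
    if source.startswith("face_"):
        _, i, axis = source.split("_")
        return signals.coords[:, point_slot(int(i)), 0 if axis == "x" else 1]
    if source.startswith("angle_33_"):
        return unwrap_degrees(signals.angle_to(int(source.rsplit("_", 1)[1])))
    if source.startswith("speed_"):
        i = point_slot(int(source.split("_")[1]))
        return np.linalg.norm(np.diff(signals.coords[:, i, :], axis=0), axis=1)
    raise KeyError(f"unknown signal source '{source}'")


def _pair_series(signals: FrameSignalSeries, source: str) -> tuple[np.ndarray, np.ndarray]:
    _, i, j, axis = source.split("_")
    k = 0 if axis == "x" else 1
    return (
        signals.coords[:, point_slot(int(i)), k],
        signals.coords[:, point_slot(int(j)), k],
    )


def build_feature_vector(
    trajectory: LandmarkTrajectory,
    manifest: FeatureManifest | None = None,
    ear_q1_reference: float | None = None,
    mar_q1_reference: float | None = None,
    *,
    signals: FrameSignalSeries | None = None,
) -> pd.Series:
    """Evaluate every manifest entry for one participant.

    ``ear_q1_reference`` / ``mar_q1_reference`` set the below-Q1 occupancy
    reference (normally the pooled training-cohort first quartile); when
    omitted the participant's own first quartile is used ("per-video"
    mode).  Undefined statistics are returned as NaN, never dropped.
    """
    manifest = manifest or default_manifest()
    if signals is None:
        signals = per_frame_signals(trajectory)
    cache: dict[str, dict[str, float]] = {}

    def stats_for(source: str) -> dict[str, float]:
        if source not in cache:
            cache[source] = {}
        return cache[source]

    values = np.empty(len(manifest))
    for k, entry in enumerate(manifest.entries):
        if entry.statistic == SPEARMAN:
            a, b = _pair_series(signals, entry.source)
            values[k] = spearman_pair(a, b)
            continue
        memo = stats_for(entry.source)
        if entry.statistic in (IQR, MAD, SPEED_MAD):
            if "iqr" not in memo:
                memo["iqr"], memo["mad"] = robust_dispersion(
                    _source_series(signals, entry.source)
                )
            values[k] = memo["iqr" if entry.statistic == IQR else "mad"]
        elif entry.statistic == OUTLIER_FRACTION:
            if "outliers" not in memo:
                memo["outliers"] = outlier_fraction(_source_series(signals, entry.source))
            values[k] = memo["outliers"]
        elif entry.statistic == PACF1:
            if "pacf" not in memo:
                memo["pacf"] = pacf_coefficient(_source_series(signals, entry.source))
            values[k] = memo["pacf"]
        elif entry.statistic == BELOW_Q1_PCT:
            series = _source_series(signals, entry.source)
            ref = ear_q1_reference if entry.source == "ear" else mar_q1_reference
            if ref is None:
                obs = series[np.isfinite(series)]
                ref = float(np.percentile(obs, 25)) if len(obs) else np.nan
            values[k] = (
                below_reference_fraction(series, ref) if np.isfinite(ref) else np.nan
            )
        else:
            raise KeyError(f"unknown statistic '{entry.statistic}'")
    return pd.Series(values, index=manifest.names, name=trajectory.participant_id)


# ---------------------------------------------------------------------------
# cohort feature table
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CohortFeatures:
    """Raw per-participant features plus the aspect-ratio frame series.

    The below-Q1 occupancy features depend on a cohort-level reference
    (the pooled first quartile of the training participants' EAR/MAR
    values), so they are kept recomputable: ``static`` holds every feature
    with the below-Q1 columns unset, and ``ear_series``/``mar_series``
    hold the raw per-frame values needed to fill them for any reference.
    """

    manifest: FeatureManifest
    static: pd.DataFrame  # participants x features, below-Q1 columns NaN
    ear_series: dict[str, np.ndarray]
    mar_series: dict[str, np.ndarray]

    @property
    def participant_ids(self) -> list[str]:
        return list(self.static.index)

    def pooled_q1(self, ids: Sequence[str]) -> tuple[float, float]:
        """Pooled first quartile of the EAR and MAR frames of ``ids``."""
        ear = np.concatenate([_clean(self.ear_series[i]) for i in ids])
        mar = np.concatenate([_clean(self.mar_series[i]) for i in ids])
        q_ear = float(np.percentile(ear, 25)) if len(ear) else np.nan
        q_mar = float(np.percentile(mar, 25)) if len(mar) else np.nan
        return q_ear, q_mar

    def table_with_reference(self, ear_q1: float, mar_q1: float) -> pd.DataFrame:
        """Full (unimputed) feature matrix under the given references."""
        out = self.static.copy()
        for src, ref, col in (
            ("ear", ear_q1, "ear_below_q1_pct"),
            ("mar", mar_q1, "mar_below_q1_pct"),
        ):
            if col not in out.columns:
                continue
            series = self.ear_series if src == "ear" else self.mar_series
            out[col] = [
                below_reference_fraction(series[i], ref) if np.isfinite(ref) else np.nan
                for i in out.index
            ]
        return out


@dataclasses.dataclass
class FeatureTable:
    """Participants x features matrix aligned to a manifest.

    ``data`` is the (possibly imputed) matrix, ``missing`` the
    pre-imputation missingness mask.  When built from trajectories the
    table keeps the raw :class:`CohortFeatures` so cross-validation can
    recompute references and imputation on training rows only.
    """

    data: pd.DataFrame
    manifest: FeatureManifest
    missing: pd.DataFrame
    raw: CohortFeatures | None = None

    def __post_init__(self) -> None:
        if list(self.data.columns) != self.manifest.names:
            raise IntegrityError("table columns must match the manifest order")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise IntegrityError(f"duplicate participant id '{dup}'")

    @property
    def participant_ids(self) -> list[str]:
        return list(self.data.index)

    def save_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.data.rename_axis("participant_id").to_csv(path)
        return path

    @classmethod
    def load_csv(cls, path: str | Path, manifest: FeatureManifest) -> "FeatureTable":
        data = pd.read_csv(path, index_col="participant_id")
        data.index = data.index.astype(str)
        return cls(data[manifest.names], manifest, data[manifest.names].isna())


def extract_cohort_features(
    trajectories: Iterable[LandmarkTrajectory],
    manifest: FeatureManifest | None = None,
    *,
    estimate_pose: bool = True,
) -> CohortFeatures:
    """Compute the reference-independent features of every participant."""
    manifest = manifest or default_manifest()
    rows: list[pd.Series] = []
    ear_series: dict[str, np.ndarray] = {}
    mar_series: dict[str, np.ndarray] = {}
    for traj in trajectories:
        if traj.participant_id in ear_series:
            raise IntegrityError(f"duplicate participant id '{traj.participant_id}'")
        signals = per_frame_signals(traj, estimate_pose=estimate_pose)
        vec = build_feature_vector(
            traj, manifest, ear_q1_reference=np.nan, mar_q1_reference=np.nan,
            signals=signals,
        )
        rows.append(vec)
        ear_series[traj.participant_id] = signals.ear
        mar_series[traj.participant_id] = signals.mar
    static = pd.DataFrame(rows)
    static.index.name = "participant_id"
    return CohortFeatures(manifest, static, ear_series, mar_series)


def impute_with_medians(
    data: pd.DataFrame, medians: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Fill missing cells with the provided (training-set) column medians;
    columns whose median is itself undefined fall back to 0."""
    if medians is None:
        medians = data.median(axis=0, skipna=True)
    medians = medians.fillna(0.0)
    return data.fillna(medians), medians


def build_feature_table(
    cohort: Iterable[LandmarkTrajectory],
    labels: CohortLabels | None = None,
    manifest: FeatureManifest | None = None,
    *,
    estimate_pose: bool = True,
    raw_features: CohortFeatures | None = None,
) -> FeatureTable:
    """Assemble the cohort feature matrix.

    The below-Q1 references are pooled over all given participants and
    missing cells imputed with cohort medians; inside cross-validation the
    same steps are instead re-run per split on training rows only (the
    table keeps the raw features to make that possible).
    """
    raw = raw_features if raw_features is not None else extract_cohort_features(
        cohort, manifest, estimate_pose=estimate_pose
    )
    if labels is not None:
        groups = labels.groups(raw.participant_ids)
        counts = pd.Series(groups).value_counts()
        if (counts < 2).any() or len(counts) < 2:
            raise ValueError("need at least 2 participants per group")
    ear_q1, mar_q1 = raw.pooled_q1(raw.participant_ids)
    data = raw.table_with_reference(ear_q1, mar_q1)
    missing = data.isna()
    constant = data.nunique(dropna=True) <= 1
    if constant.any():
        import warnings

        warnings.warn(
            f"{int(constant.sum())} feature column(s) are constant across the cohort",
            stacklevel=2,
        )
    data, _ = impute_with_medians(data)
    return FeatureTable(data, raw.manifest, missing, raw)
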