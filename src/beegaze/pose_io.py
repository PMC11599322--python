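"""Reading, writing and quality-filtering of multi-animal pose tracks.

Tracks arrive as the pose-estimator CSV dialect with a 3-row column header
(animal / bodypart / coordinate-or-likelihood) over a leading frame-index
column, one row per video frame.  Coordinates are in video pixels and are
converted to arena centimetres through a linear calibration (scale +
origin).  An optional HDF5 twin stores the same table.

Frame-quality filtering mirrors the study's protocol: wall/ceiling episodes
are excluded via an explicit per-frame flag (supplied as a flag column or a
frame-range mask file, replacing the study's manual scoring), then frames
whose head or thorax likelihood falls below 0.99 are dropped, then frames
whose head-thorax separation is too short to define a body axis.  Frames are
never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BODYPARTS",
    "Calibration",
    "FilterConfig",
    "PoseTrack",
    "FilteredTrack",
    "FormatError",
    "CalibrationError",
    "load_pose_tracks",
    "write_pose_tracks",
    "load_exclusion_mask",
    "apply_filters",
]

BODYPARTS = ("head", "thorax", "abdomen")
_COORDS = ("x", "y", "likelihood")

#: Validity reasons, in precedence order (first matching reason wins).
REASON_OK = "ok"
REASON_WALL = "wall_ceiling"
REASON_MISSING = "missing"
REASON_LOW_LIKELIHOOD = "low_likelihood"
REASON_DEGENERATE = "degenerate_pose"


class FormatError(ValueError):
    """Pose-track file does not match the expected dialect."""


class CalibrationError(ValueError):
    """Pixel-to-cm calibration is unusable."""


@dataclass(frozen=True)
class Calibration:
    """Linear pixel -> cm mapping: ``cm = (px - origin) / px_per_cm``."""

    px_per_cm: float = 1.0
    origin_x_px: float = 0.0
    origin_y_px: float = 0.0

    def __post_init__(self) -> None:
        if not self.px_per_cm > 0:
            raise CalibrationError("px_per_cm must be positive")

    def to_cm(self, x_px: np.ndarray, y_px: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return ((np.asarray(x_px, float) - self.origin_x_px) / self.px_per_cm,
                (np.asarray(y_px, float) - self.origin_y_px) / self.px_per_cm)

    def to_px(self, x_cm: np.ndarray, y_cm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return (np.asarray(x_cm, float) * self.px_per_cm + self.origin_x_px,
                np.asarray(y_cm, float) * self.px_per_cm + self.origin_y_px)


@dataclass(frozen=True)
class FilterConfig:
    """Frame-quality thresholds.

    ``likelihood_threshold`` follows the study protocol (0.99); frames with
    head or thorax below it are dropped.  ``min_body_axis`` (cm) is the
    minimum head-thorax separation that still defines a heading.
    """

    likelihood_threshold: float = 0.99
    min_body_axis: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.likelihood_threshold <= 1:
            raise ValueError("likelihood_threshold must be in (0, 1]")
        if self.min_body_axis < 0:
            raise ValueError("min_body_axis must be non-negative")


@dataclass
class PoseTrack:
    """Calibrated per-frame keypoints for one animal.

    ``data`` holds, per bodypart, x/y in cm and the estimator's likelihood;
    missing keypoints are NaN coordinates with likelihood 0.
    ``excluded_flag`` marks wall/ceiling episodes.
    """

    animal_id: str
    frame_index: np.ndarray  # (n,) strictly increasing int64
    data: dict[str, dict[str, np.ndarray]]  # bodypart -> {x, y, likelihood}
    fps: float = 100.0
    excluded_flag: np.ndarray | None = None  # (n,) bool

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        if len(self.frame_index) and np.any(np.diff(self.frame_index) <= 0):
            raise ValueError("frame_index must be strictly increasing")
        if self.excluded_flag is None:
            self.excluded_flag = np.zeros(len(self.frame_index), dtype=bool)
        else:
            self.excluded_flag = np.asarray(self.excluded_flag, dtype=bool)
        for bp in BODYPARTS:
            if bp not in self.data:
                raise ValueError(f"missing bodypart {bp!r}")
            lk = np.asarray(self.data[bp]["likelihood"], dtype=float)
            if np.any((lk < 0) | (lk > 1)):
                raise ValueError("likelihood must lie in [0, 1]")
            self.data[bp]["likelihood"] = lk

    def __len__(self) -> int:
        return len(self.frame_index)

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)


@dataclass
class FilteredTrack:
    """A PoseTrack plus per-frame validity and the reason for exclusion."""

    track: PoseTrack
    valid: np.ndarray  # (n,) bool
    exclusion_reason: np.ndarray  # (n,) object/str

    @property
    def valid_fraction(self) -> float:
        return float(np.mean(self.valid)) if len(self.valid) else 0.0

    def reason_fractions(self) -> dict[str, float]:
        reasons, counts = np.unique(self.exclusion_reason, return_counts=True)
        n = max(len(self.exclusion_reason), 1)
        return {str(r): c / n for r, c in zip(reasons, counts)}


# ---------------------------------------------------------------------------
# CSV / HDF5 round trip
# ---------------------------------------------------------------------------

def _tracks_to_frame(tracks: dict[str, PoseTrack],
                     calibration: Calibration) -> pd.DataFrame:
    frames = None
    cols = {}
    for animal, track in tracks.items():
        if frames is None:
            frames = track.frame_index
        elif not np.array_equal(frames, track.frame_index):
            raise FormatError("animals must share frame indexing")
        for bp in BODYPARTS:
            x_px, y_px = calibration.to_px(track.data[bp]["x"], track.data[bp]["y"])
            cols[(animal, bp, "x")] = x_px
            cols[(animal, bp, "y")] = y_px
            cols[(animal, bp, "likelihood")] = track.data[bp]["likelihood"]
        if track.excluded_flag is not None and np.any(track.excluded_flag):
            cols[(animal, "meta", "excluded")] = track.excluded_flag.astype(int)
    df = pd.DataFrame(cols, index=pd.Index(frames, name="frame"))
    df.columns = pd.MultiIndex.from_tuples(df.columns,
                                           names=["animal", "bodypart", "coord"])
    return df


def write_pose_tracks(path: str | Path, tracks: dict[str, PoseTrack],
                      calibration: Calibration = Calibration()) -> None:
    """Write tracks in the 3-row-header CSV dialect (or HDF5 for .h5 paths)."""
    path = Path(path)
    df = _tracks_to_frame(tracks, calibration)
    if path.suffix in (".h5", ".hdf5"):
        df.to_hdf(path, key="pose_tracks", mode="w")
    else:
        df.to_csv(path, float_format="%.6f")


def load_pose_tracks(path: str | Path,
                     calibration: Calibration = Calibration(),
                     fps: float = 100.0) -> dict[str, PoseTrack]:
    """Read a multi-animal pose-track file into calibrated PoseTracks.

    Empty coordinate cells become NaN with likelihood forced to 0.  The
    optional ``(animal, meta, excluded)`` column carries the wall/ceiling
    flag.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        df = pd.read_hdf(path, key="pose_tracks")
    else:
        try:
            df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        except (ValueError, pd.errors.ParserError) as exc:
            raise FormatError(f"cannot parse {path.name}: {exc}") from exc
    if df.columns.nlevels != 3:
        raise FormatError("expected a 3-level animal/bodypart/coord header")

    tracks: dict[str, PoseTrack] = {}
    frames = df.index.to_numpy(dtype=np.int64)
    for animal in df.columns.get_level_values(0).unique():
        sub = df[animal]
        data: dict[str, dict[str, np.ndarray]] = {}
        for bp in BODYPARTS:
            if bp not in sub.columns.get_level_values(0):
                raise FormatError(f"animal {animal!r} lacks bodypart {bp!r}")
            x_px = pd.to_numeric(sub[(bp, "x")], errors="coerce").to_numpy(float)
            y_px = pd.to_numeric(sub[(bp, "y")], errors="coerce").to_numpy(float)
            lk = pd.to_numeric(sub[(bp, "likelihood")], errors="coerce").to_numpy(float)
            missing = np.isnan(x_px) | np.isnan(y_px)
            lk = np.where(missing | np.isnan(lk), 0.0, lk)
            x_cm, y_cm = calibration.to_cm(x_px, y_px)
            data[bp] = {"x": x_cm, "y": y_cm, "likelihood": lk}
        flag = None
        if ("meta", "excluded") in sub.columns:
            flag = pd.to_numeric(sub[("meta", "excluded")],
                                 errors="coerce").fillna(0).to_numpy() > 0
        tracks[str(animal)] = PoseTrack(
            animal_id=str(animal), frame_index=frames, data=data,
            fps=fps, excluded_flag=flag,
        )
    return tracks


def load_exclusion_mask(path: str | Path, n_frames: int) -> np.ndarray:
    """Read a frame-range mask CSV with columns start_frame, end_frame
    (closed ranges) into a per-frame boolean flag."""
    ranges = pd.read_csv(path)
    for col in ("start_frame", "end_frame"):
        if col not in ranges.columns:
            raise FormatError(f"mask file lacks column {col!r}")
    flag = np.zeros(n_frames, dtype=bool)
    for start, end in ranges[["start_frame", "end_frame"]].itertuples(index=False):
        if end < start:
            raise FormatError("mask range end before start")
        flag[max(int(start), 0):int(end) + 1] = True
    return flag


# ---------------------------------------------------------------------------
# Frame-quality filtering
# ---------------------------------------------------------------------------

def apply_filters(track: PoseTrack, cfg: FilterConfig = FilterConfig(),
                  exclusion_flag: np.ndarray | None = None) -> FilteredTrack:
    """Classify each frame as valid or excluded, with one reason per frame.

    Precedence: wall/ceiling flag, then missing head/thorax keypoints, then
    sub-threshold head/thorax likelihood, then degenerate (too-short) body
    axis.  The abdomen never gates validity: headings need only head and
    thorax.  Filtering is idempotent by construction.
    """
    if track.n_frames == 0:
        raise ValueError("track is empty")
    flag = track.excluded_flag if exclusion_flag is None else np.asarray(
        exclusion_flag, dtype=bool)
    head, thorax = track.data["head"], track.data["thorax"]
    missing = (np.isnan(head["x"]) | np.isnan(head["y"])
               | np.isnan(thorax["x"]) | np.isnan(thorax["y"]))
    low_lk = (head["likelihood"] < cfg.likelihood_threshold) | (
        thorax["likelihood"] < cfg.likelihood_threshold)
    with np.errstate(invalid="ignore"):
        axis_len = np.hypot(head["x"] - thorax["x"], head["y"] - thorax["y"])
    degenerate = ~missing & (axis_len < cfg.min_body_axis)

    reason = np.full(track.n_frames, REASON_OK, dtype=object)
    reason[degenerate] = REASON_DEGENERATE
    reason[low_lk] = REASON_LOW_LIKELIHOOD
    reason[missing] = REASON_MISSING
    reason[flag] = REASON_WALL
    valid = reason == REASON_OK
    return FilteredTrack(track=track, valid=valid, exclusion_reason=reason)
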