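"""Arena geometry and per-frame flower-facing classification.

The apparatus is modelled in a 2D top-down frame: the back (flower) wall is
the line ``y = 0`` with ``x`` running along it, the feeding area occupies
``0 <= y <= screen_offset``, and the transparent screen at
``y = screen_offset`` separates it from the observation chamber
(``screen_offset < y <= arena_depth``).  Flowers are wall-mounted boxes whose
visual target is their x-interval on the back wall.

A frame is "flower-facing" when the ray cast from the observer's thorax along
its body axis (thorax -> head) intersects the back wall inside a flower's
interval.  The label additionally encodes whether that flower is rewarding
(the colour the session's demonstrator was trained to) and whether the
demonstrator currently occupies it.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "TWO_PI",
    "FacingLabel",
    "FlowerSpec",
    "ArenaSpec",
    "Pose2D",
    "OccupancyFrame",
    "DegeneratePoseError",
    "PoseOutsideChamberError",
    "default_arena",
    "normalize_angle",
    "compute_heading",
    "compute_occupancy",
    "classify_facing",
    "classify_frames",
]

TWO_PI = 2.0 * math.pi

#: Minimum head-thorax separation (cm) below which a heading is undefined.
DEFAULT_MIN_BODY_AXIS = 0.05

#: Default dilation radius (cm) around a flower footprint that counts as
#: "occupied" by the demonstrator -- roughly one bee body length.
DEFAULT_OCCUPANCY_RADIUS = 1.0


class DegeneratePoseError(ValueError):
    """Head and thorax are too close to define a body axis."""


class PoseOutsideChamberError(ValueError):
    """Observer pose lies outside the observation chamber (tracking fault)."""


class FacingLabel(enum.IntEnum):
    """Per-frame facing category.

    The four flower categories cross the flower's reward status with the
    demonstrator's occupancy of it; ``NO_FLOWER`` covers frames whose facing
    ray misses every flower and ``INVALID`` covers filtered-out frames.
    """

    OCC_REWARD = 0
    UNOCC_REWARD = 1
    OCC_NONREWARD = 2
    UNOCC_NONREWARD = 3
    NO_FLOWER = 4
    INVALID = 5


#: The four flower-facing categories, in reporting order.
FLOWER_CATEGORIES = (
    FacingLabel.OCC_REWARD,
    FacingLabel.UNOCC_REWARD,
    FacingLabel.OCC_NONREWARD,
    FacingLabel.UNOCC_NONREWARD,
)


@dataclass(frozen=True)
class FlowerSpec:
    """One wall-mounted artificial flower."""

    flower_id: str
    center_x: float
    colour: str  # {"blue", "yellow", "grey"}
    rewarding: bool

    def interval(self, flower_width: float) -> tuple[float, float]:
        half = flower_width / 2.0
        return (self.center_x - half, self.center_x + half)


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry of the chamber, screen and flower array (all lengths in cm).

    ``arena_width`` runs along the back wall (x axis), ``arena_depth`` along
    the screen axis (y); the screen sits ``screen_offset`` from the back wall
    and confines the observer to ``y > screen_offset``.
    """

    arena_width: float = 15.2
    arena_depth: float = 12.8
    screen_offset: float = 2.8
    flower_width: float = 2.4
    flower_depth: float = 0.8
    flower_gap: float = 1.6
    flowers: tuple[FlowerSpec, ...] = ()
    fps: float = 100.0

    def __post_init__(self) -> None:
        for name in ("arena_width", "arena_depth", "screen_offset",
                     "flower_width", "flower_depth", "flower_gap", "fps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.screen_offset >= self.arena_depth:
            raise ValueError("screen_offset must be smaller than arena_depth")
        ivals = sorted(f.interval(self.flower_width) for f in self.flowers)
        for lo, hi in ivals:
            if lo < -1e-9 or hi > self.arena_width + 1e-9:
                raise ValueError("flower interval extends beyond the wall")
        for (_, hi), (lo, _) in zip(ivals, ivals[1:]):
            if lo < hi - 1e-9:
                raise ValueError("flower intervals overlap")

    @property
    def flower_intervals(self) -> np.ndarray:
        """(n_flowers, 2) array of [left, right] wall intervals, flower order."""
        return np.array([f.interval(self.flower_width) for f in self.flowers],
                        dtype=float).reshape(-1, 2)

    def with_flowers(self, flowers: Sequence[FlowerSpec]) -> "ArenaSpec":
        return replace(self, flowers=tuple(flowers))


@dataclass(frozen=True)
class Pose2D:
    """Thorax position (cm) and body-axis heading, CCW from +x, in (-pi, pi]."""

    x: float
    y: float
    heading: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "heading", normalize_angle(self.heading))


@dataclass(frozen=True)
class OccupancyFrame:
    """Which flowers the demonstrator occupies on one frame."""

    frame_index: int
    occupied: tuple[bool, ...]

    def __post_init__(self) -> None:
        if sum(self.occupied) > 1:
            raise ValueError("at most one flower may be occupied per frame")


def normalize_angle(theta: float) -> float:
    """Wrap an angle into (-pi, pi]."""
    wrapped = math.remainder(theta, TWO_PI)
    if wrapped <= -math.pi:
        wrapped += TWO_PI
    return wrapped


def default_arena(
    demonstrated_colour: str = "blue",
    colours: Sequence[str] = ("blue", "yellow", "yellow", "blue"),
) -> ArenaSpec:
    """The study apparatus: 15.2 x 12.8 cm arena, screen 2.8 cm from the wall,
    four 2.4 cm flowers separated by 1.6 cm, the array centred on the wall.

    ``demonstrated_colour`` sets which flowers are rewarding for the session;
    ``colours`` assigns colours left-to-right (default alternating, two blue
    and two yellow).
    """
    spec = ArenaSpec()
    if len(colours) != 4:
        raise ValueError("the default arena carries exactly four flowers")
    pitch = spec.flower_width + spec.flower_gap
    span = 4 * spec.flower_width + 3 * spec.flower_gap
    first_center = (spec.arena_width - span) / 2.0 + spec.flower_width / 2.0
    flowers = tuple(
        FlowerSpec(
            flower_id=f"F{i}",
            center_x=first_center + i * pitch,
            colour=c,
            rewarding=(c == demonstrated_colour),
        )
        for i, c in enumerate(colours)
    )
    return spec.with_flowers(flowers)


def compute_heading(
    thorax: tuple[float, float],
    head: tuple[float, float],
    min_body_axis: float = DEFAULT_MIN_BODY_AXIS,
) -> float:
    """Body-axis angle of the thorax->head vector, wrapped to (-pi, pi].

    Raises :class:`DegeneratePoseError` when the two keypoints are closer
    than ``min_body_axis`` cm, in which case the frame is invalid downstream.
    """
    dx = head[0] - thorax[0]
    dy = head[1] - thorax[1]
    if math.hypot(dx, dy) < min_body_axis:
        raise DegeneratePoseError(
            f"head-thorax distance {math.hypot(dx, dy):.4g} cm below "
            f"min_body_axis {min_body_axis:g} cm"
        )
    return normalize_angle(math.atan2(dy, dx))


def compute_occupancy(
    demonstrator_pose: Pose2D | tuple[float, float] | None,
    arena: ArenaSpec,
    radius: float = DEFAULT_OCCUPANCY_RADIUS,
) -> OccupancyFrame:
    """Mark each flower occupied iff the demonstrator thorax lies within the
    flower's footprint rectangle dilated by ``radius`` cm.

    An absent demonstrator (``None``, e.g. returned to the tunnel) leaves all
    flowers unoccupied.
    """
    if radius <= 0:
        raise ValueError("occupancy radius must be positive")
    n = len(arena.flowers)
    if demonstrator_pose is None:
        return OccupancyFrame(frame_index=-1, occupied=(False,) * n)
    if isinstance(demonstrator_pose, Pose2D):
        px, py = demonstrator_pose.x, demonstrator_pose.y
    else:
        px, py = demonstrator_pose
    occupied = []
    for flower in arena.flowers:
        lo, hi = flower.interval(arena.flower_width)
        inside = (lo - radius <= px <= hi + radius) and (
            -radius <= py <= arena.flower_depth + radius
        )
        occupied.append(inside)
    # A point deep in a gap can fall inside two dilated footprints when
    # 2*radius exceeds the gap (true at the defaults: 2.0 > 1.6); the
    # demonstrator can only feed at one flower, so ties go to the nearest
    # flower center.
    if sum(occupied) > 1:
        dists = [
            abs(px - f.center_x) if occ else math.inf
            for f, occ in zip(arena.flowers, occupied)
        ]
        nearest = dists.index(min(dists))
        occupied = [i == nearest for i in range(len(occupied))]
    return OccupancyFrame(frame_index=-1, occupied=tuple(occupied))


def _ray_wall_x(x: float, y: float, heading: float) -> float | None:
    """x-coordinate where the ray from (x, y) along ``heading`` meets y = 0,
    or None when the ray points away from (or parallel to) the wall."""
    sin_h = math.sin(heading)
    if sin_h >= 0.0:
        return None
    return x + y * math.cos(heading) / (-sin_h)


def classify_facing(
    observer: Pose2D,
    occupancy: OccupancyFrame,
    arena: ArenaSpec,
) -> FacingLabel:
    """Classify one valid observer frame into a facing category.

    The ray from the observer thorax along its heading is intersected with
    the back wall (y = 0); a hit inside a flower's closed x-interval yields
    the label formed by that flower's reward flag crossed with its occupancy,
    otherwise ``NO_FLOWER``.  Rays pointing away from the wall always miss.
    """
    if observer.y <= arena.screen_offset:
        raise PoseOutsideChamberError(
            f"observer y={observer.y:.3g} cm is not inside the observation "
            f"chamber (screen at y={arena.screen_offset:g} cm)"
        )
    x_star = _ray_wall_x(observer.x, observer.y, observer.heading)
    if x_star is None:
        return FacingLabel.NO_FLOWER
    for i, flower in enumerate(arena.flowers):
        lo, hi = flower.interval(arena.flower_width)
        if lo <= x_star <= hi:  # closed interval: endpoint counts as a hit
            occ = occupancy.occupied[i]
            if flower.rewarding:
                return FacingLabel.OCC_REWARD if occ else FacingLabel.UNOCC_REWARD
            return FacingLabel.OCC_NONREWARD if occ else FacingLabel.UNOCC_NONREWARD
    return FacingLabel.NO_FLOWER


# ---------------------------------------------------------------------------
# Vectorised kernels used by metrics.label_session and the synthetic generator
# ---------------------------------------------------------------------------

def facing_flower_index(
    x: np.ndarray, y: np.ndarray, heading: np.ndarray, arena: ArenaSpec
) -> np.ndarray:
    """Vectorised ray cast: per-frame index of the flower hit, -1 for a miss.

    Inputs are equal-length arrays of thorax coordinates (cm) and headings
    (radians).  Frames at or behind the screen line are the caller's
    responsibility; the ray test itself only needs y > 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    heading = np.asarray(heading, dtype=float)
    sin_h = np.sin(heading)
    toward = sin_h < 0.0
    x_star = np.full_like(x, np.nan)
    np.divide(y * np.cos(heading), -sin_h, out=x_star, where=toward)
    x_star = np.where(toward, x + x_star, np.nan)

    intervals = arena.flower_intervals
    order = np.argsort(intervals[:, 0])
    lefts = intervals[order, 0]
    rights = intervals[order, 1]
    # closed intervals: searchsorted(side="right") keeps x* == left inside
    pos = np.searchsorted(lefts, np.nan_to_num(x_star, nan=-np.inf),
                          side="right") - 1
    hit = toward & (pos >= 0)
    pos_clip = np.clip(pos, 0, len(lefts) - 1)
    hit &= x_star <= rights[pos_clip]
    # x* exactly on a right endpoint that equals the next left endpoint cannot
    # happen: intervals are disjoint with positive gaps by ArenaSpec invariant.
    result = np.where(hit, order[pos_clip], -1)
    return result.astype(np.int64)


def occupancy_matrix(
    demo_x: np.ndarray,
    demo_y: np.ndarray,
    present: np.ndarray,
    arena: ArenaSpec,
    radius: float = DEFAULT_OCCUPANCY_RADIUS,
) -> np.ndarray:
    """Vectorised occupancy: (n_frames, n_flowers) boolean matrix.

    ``present`` masks frames where the demonstrator has a usable thorax fix;
    absent frames leave every flower unoccupied.
    """
    if radius <= 0:
        raise ValueError("occupancy radius must be positive")
    demo_x = np.asarray(demo_x, dtype=float)
    demo_y = np.asarray(demo_y, dtype=float)
    present = np.asarray(present, dtype=bool)
    intervals = arena.flower_intervals
    in_y = (demo_y >= -radius) & (demo_y <= arena.flower_depth + radius)
    occ = (
        (demo_x[:, None] >= intervals[None, :, 0] - radius)
        & (demo_x[:, None] <= intervals[None, :, 1] + radius)
        & (in_y & present)[:, None]
    )
    # nearest-center tie-break for frames inside two dilated footprints
    multi = occ.sum(axis=1) > 1
    if np.any(multi):
        centers = np.array([f.center_x for f in arena.flowers], dtype=float)
        dist = np.abs(demo_x[multi, None] - centers[None, :])
        dist[~occ[multi]] = np.inf
        nearest = np.argmin(dist, axis=1)
        occ[multi] = False
        occ[np.flatnonzero(multi), nearest] = True
    return occ


def classify_frames(
    x: np.ndarray,
    y: np.ndarray,
    heading: np.ndarray,
    valid: np.ndarray,
    occupied: np.ndarray,
    arena: ArenaSpec,
) -> np.ndarray:
    """Vectorised facing classification for a whole session.

    ``occupied`` is the (n_frames, n_flowers) occupancy matrix; invalid
    frames come out as ``INVALID``.  Raises
    :class:`PoseOutsideChamberError` if any valid frame sits at or behind
    the screen line.
    """
    valid = np.asarray(valid, dtype=bool)
    y = np.asarray(y, dtype=float)
    if np.any(valid & (y <= arena.screen_offset)):
        raise PoseOutsideChamberError(
            "valid observer frame at or behind the screen line"
        )
    labels = np.full(len(y), int(FacingLabel.INVALID), dtype=np.int64)
    if not np.any(valid):
        return labels
    idx = facing_flower_index(x, y, heading, arena)
    rewarding = np.array([f.rewarding for f in arena.flowers], dtype=bool)
    hit = valid & (idx >= 0)
    labels[valid] = int(FacingLabel.NO_FLOWER)
    if np.any(hit):
        fi = idx[hit]
        occ = occupied[np.flatnonzero(hit), fi]
        rew = rewarding[fi]
        cat = np.where(
            rew,
            np.where(occ, int(FacingLabel.OCC_REWARD), int(FacingLabel.UNOCC_REWARD)),
            np.where(occ, int(FacingLabel.OCC_NONREWARD),
                     int(FacingLabel.UNOCC_NONREWARD)),
        )
        labels[hit] = cat
    return labels
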