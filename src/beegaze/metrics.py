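"""Session-level behaviour summaries built on per-frame facing labels.

Turns a pair of filtered tracks (observer + demonstrator) into the study's
summaries: per-category facing seconds, facing bouts with short-dropout
bridging, the preceding-category tally for bouts of facing an unoccupied
rewarding flower, and positional / heading-direction histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arena import (
    ArenaSpec,
    FacingLabel,
    DEFAULT_OCCUPANCY_RADIUS,
    classify_frames,
    occupancy_matrix,
)
from .pose_io import FilteredTrack

__all__ = [
    "FacingSummary",
    "Bout",
    "TransitionCounts",
    "FrameAlignmentError",
    "compute_headings",
    "label_session",
    "summarize_facing",
    "segment_bouts",
    "preceding_category_counts",
    "spatial_heading_histograms",
]

DEFAULT_MAX_BRIDGE_FRAMES = 5  # 50 ms at 100 fps


class FrameAlignmentError(ValueError):
    """Observer and demonstrator tracks disagree on frame indexing."""


@dataclass(frozen=True)
class FacingSummary:
    """Per-bee seconds in each facing category over one observation session.

    The six times partition the session exactly: their frame counts sum to
    the session's frame count.
    """

    bee_id: str
    group: str
    colony_id: str
    t_occ_reward: float
    t_unocc_reward: float
    t_occ_nonreward: float
    t_unocc_nonreward: float
    t_no_flower: float
    t_invalid: float
    session_duration: float

    @property
    def t_reward(self) -> float:
        return self.t_occ_reward + self.t_unocc_reward

    @property
    def t_nonreward(self) -> float:
        return self.t_occ_nonreward + self.t_unocc_nonreward

    def facing_times(self) -> dict[str, float]:
        return {
            "t_occ_reward": self.t_occ_reward,
            "t_unocc_reward": self.t_unocc_reward,
            "t_occ_nonreward": self.t_occ_nonreward,
            "t_unocc_nonreward": self.t_unocc_nonreward,
        }


@dataclass(frozen=True)
class Bout:
    """Maximal run of one facing label; frames are closed [start, end]."""

    label: FacingLabel
    start_frame: int
    end_frame: int

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass(frozen=True)
class TransitionCounts:
    """What the observer faced just before an unoccupied-rewarding bout."""

    bee_id: str
    n_preceded_by_nonreward: int
    n_preceded_by_occ_reward: int
    n_preceded_by_other: int

    @property
    def total(self) -> int:
        return (self.n_preceded_by_nonreward + self.n_preceded_by_occ_reward
                + self.n_preceded_by_other)


def compute_headings(track: FilteredTrack, min_body_axis: float = 0.05
                     ) -> np.ndarray:
    """Per-frame thorax->head angles (radians, NaN where undefined)."""
    head = track.track.data["head"]
    thorax = track.track.data["thorax"]
    dx = head["x"] - thorax["x"]
    dy = head["y"] - thorax["y"]
    with np.errstate(invalid="ignore"):
        heading = np.arctan2(dy, dx)
        heading[np.hypot(dx, dy) < min_body_axis] = np.nan
    return heading


def label_session(
    observer: FilteredTrack,
    demonstrator: FilteredTrack | None,
    arena: ArenaSpec,
    occupancy_radius: float = DEFAULT_OCCUPANCY_RADIUS,
    demonstrator_invalid_is_unoccupied: bool = True,
) -> np.ndarray:
    """Per-frame FacingLabel codes for one observation session.

    Invalid observer frames become ``INVALID``.  Demonstrator frames that
    are invalid (or an absent demonstrator track) default to "all flowers
    unoccupied", since the facing geometry is still defined; set
    ``demonstrator_invalid_is_unoccupied=False`` to mark those observer
    frames ``INVALID`` instead.
    """
    obs = observer.track
    n = obs.n_frames
    if demonstrator is not None:
        demo = demonstrator.track
        if not np.array_equal(obs.frame_index, demo.frame_index):
            raise FrameAlignmentError(
                "observer and demonstrator tracks must share frame indexing")
        occ = occupancy_matrix(
            demo.data["thorax"]["x"], demo.data["thorax"]["y"],
            present=demonstrator.valid, arena=arena, radius=occupancy_radius)
    else:
        occ = np.zeros((n, len(arena.flowers)), dtype=bool)

    heading = compute_headings(observer)
    valid = observer.valid & ~np.isnan(heading)
    labels = classify_frames(
        obs.data["thorax"]["x"], obs.data["thorax"]["y"], heading,
        valid=valid, occupied=occ, arena=arena)
    if demonstrator is not None and not demonstrator_invalid_is_unoccupied:
        labels[~demonstrator.valid] = int(FacingLabel.INVALID)
    return labels


def summarize_facing(labels: np.ndarray, fps: float, bee_id: str = "",
                     group: str = "", colony_id: str = "") -> FacingSummary:
    """Seconds per facing category: frame counts / fps.

    Conservation holds exactly in frames: the six counts sum to len(labels).
    """
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("label sequence is empty")
    counts = np.bincount(labels, minlength=len(FacingLabel))
    return FacingSummary(
        bee_id=bee_id, group=group, colony_id=colony_id,
        t_occ_reward=counts[FacingLabel.OCC_REWARD] / fps,
        t_unocc_reward=counts[FacingLabel.UNOCC_REWARD] / fps,
        t_occ_nonreward=counts[FacingLabel.OCC_NONREWARD] / fps,
        t_unocc_nonreward=counts[FacingLabel.UNOCC_NONREWARD] / fps,
        t_no_flower=counts[FacingLabel.NO_FLOWER] / fps,
        t_invalid=counts[FacingLabel.INVALID] / fps,
        session_duration=len(labels) / fps,
    )


def segment_bouts(labels: np.ndarray,
                  max_bridge_frames: int = DEFAULT_MAX_BRIDGE_FRAMES
                  ) -> list[Bout]:
    """Maximal runs of identical non-INVALID labels.

    INVALID gaps of at most ``max_bridge_frames`` frames sandwiched between
    runs of the same label are bridged into one bout (short tracking
    dropouts should not split a fixation); longer gaps, or gaps between
    different labels, split bouts.  Bridged INVALID frames count toward the
    bout's duration.
    """
    labels = np.asarray(labels)
    runs: list[tuple[int, int, int]] = []  # (label, start, end)
    if len(labels):
        change = np.flatnonzero(np.diff(labels)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change - 1, [len(labels) - 1]))
        runs = [(int(labels[s]), int(s), int(e)) for s, e in zip(starts, ends)]

    bouts: list[Bout] = []
    i = 0
    while i < len(runs):
        lab, start, end = runs[i]
        if lab == int(FacingLabel.INVALID):
            i += 1
            continue
        # absorb INVALID gaps <= max_bridge_frames followed by the same label
        j = i
        while (j + 2 < len(runs)
               and runs[j + 1][0] == int(FacingLabel.INVALID)
               and runs[j + 1][2] - runs[j + 1][1] + 1 <= max_bridge_frames
               and runs[j + 2][0] == lab):
            j += 2
            end = runs[j][2]
        bouts.append(Bout(label=FacingLabel(lab), start_frame=start,
                          end_frame=end))
        i = j + 1
    return bouts


def preceding_category_counts(bouts: list[Bout], bee_id: str = ""
                              ) -> TransitionCounts:
    """Tally what immediately preceded each unoccupied-rewarding bout.

    For every UNOCC_REWARD bout with a predecessor bout, the predecessor's
    label falls into non-rewarding (either non-rewarding category), occupied
    rewarding, or other (NO_FLOWER).  Session-initial bouts have no
    predecessor and are excluded.
    """
    n_non = n_occ = n_other = 0
    for prev, cur in zip(bouts, bouts[1:]):
        if cur.label is not FacingLabel.UNOCC_REWARD:
            continue
        if prev.label in (FacingLabel.OCC_NONREWARD, FacingLabel.UNOCC_NONREWARD):
            n_non += 1
        elif prev.label is FacingLabel.OCC_REWARD:
            n_occ += 1
        else:
            n_other += 1
    return TransitionCounts(bee_id=bee_id, n_preceded_by_nonreward=n_non,
                            n_preceded_by_occ_reward=n_occ,
                            n_preceded_by_other=n_other)


def spatial_heading_histograms(
    track: FilteredTrack,
    arena: ArenaSpec,
    position_bins: tuple[int, int] = (16, 16),
    heading_bins: int = 36,
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Normalised chamber-occupancy histogram and circular heading rose.

    Only valid frames with a defined heading contribute; each histogram sums
    to 1.  Returns ``(position_hist, heading_hist, edges)`` where
    ``position_hist`` has shape ``position_bins`` (x-bin major) over the
    chamber ``[0, arena_width] x [screen_offset, arena_depth]`` and
    ``heading_hist`` covers ``(-pi, pi]``.
    """
    heading = compute_headings(track)
    valid = track.valid & ~np.isnan(heading)
    if not np.any(valid):
        raise ValueError("no valid frames to histogram")
    x = track.track.data["thorax"]["x"][valid]
    y = track.track.data["thorax"]["y"][valid]
    pos_hist, x_edges, y_edges = np.histogram2d(
        x, y, bins=position_bins,
        range=[[0.0, arena.arena_width],
               [arena.screen_offset, arena.arena_depth]])
    pos_hist /= pos_hist.sum()
    h_edges = np.linspace(-np.pi, np.pi, heading_bins + 1)
    h_hist, _ = np.histogram(heading[valid], bins=h_edges)
    h_hist = h_hist / h_hist.sum()
    edges = {"x": x_edges, "y": y_edges, "heading": h_edges}
    return pos_hist, h_hist, edges
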