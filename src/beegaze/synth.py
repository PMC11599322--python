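"""Synthetic observation sessions and test-phase choices with ground truth.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage is testable without the study's videos:

* a demonstrator executing a truncated-normal number of flower visits
  (default 11.333 +/- 2.270, at least one) on the rewarding flowers, with a
  small per-visit error probability of landing on a non-rewarding flower;
  feeding is dwell at the flower face, inter-flower travel a straight line
  deeper in the feeding area (outside the occupancy dilation);
* an observer whose attention alternates between flower categories and
  off-target wandering (an alternating-renewal schedule with gamma dwell
  times), whose position relaxes toward the attended target (and toward the
  screen) as a discrete Ornstein-Uhlenbeck walk, and whose heading points
  at the attended target with von Mises concentration kappa;
* pose-estimator artefacts: Beta-distributed keypoint likelihoods with rare
  dropouts, and wall/ceiling episodes flagging about 15% of observer frames;
* per-bee choice counts drawn from a logistic model combining an innate
  blue bias with facing-time effects.

Attention is scheduled in *category* terms conditioned on the realised
demonstrator occupancy (category weights are inflated by the inverse of the
time share in which the category is realisable), so the scheduled dwell
fractions are also the expected realised fractions, and ground-truth labels
are unambiguous even with heading noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

from .arena import ArenaSpec, FacingLabel, default_arena
from .pose_io import BODYPARTS, Calibration, PoseTrack, write_pose_tracks

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "ConfigError",
    "simulate_session",
    "simulate_choices",
    "simulate_choice_counts",
    "simulate_facing_summaries",
    "make_fixture_suite",
]

CATEGORIES = ("occ_reward", "unocc_reward", "occ_nonreward", "unocc_nonreward")
_CAT_TO_LABEL = {
    "occ_reward": FacingLabel.OCC_REWARD,
    "unocc_reward": FacingLabel.UNOCC_REWARD,
    "occ_nonreward": FacingLabel.OCC_NONREWARD,
    "unocc_nonreward": FacingLabel.UNOCC_NONREWARD,
    "off": FacingLabel.NO_FLOWER,
}


class ConfigError(ValueError):
    """Generator configuration violates an invariant."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic session generator.

    Defaults follow the study's printed descriptive statistics where they
    exist (session durations uniform on 94-288 s, 100 fps, 11.333 +/- 2.270
    demonstrator visits, ~15% wall/ceiling-flagged frames) and otherwise
    hold values chosen as realistic for walking bumblebees in a 2-cm-high
    arena.
    """

    seed: int = 0
    n_bees_per_group: int = 22
    session_duration_s: tuple[float, float] = (94.0, 288.0)
    fps: float = 100.0
    # attention: mean time fractions per facing category; the remainder is
    # off-target.  Defaults echo the study's bees facing flowers for roughly
    # a quarter of the session, mostly the rewarding ones.
    attention_weights: dict[str, float] = field(default_factory=lambda: {
        "occ_reward": 0.10, "unocc_reward": 0.08,
        "occ_nonreward": 0.01, "unocc_nonreward": 0.05,
    })
    #: Dirichlet precision for per-bee variation of attention fractions.
    attention_concentration: float = 8.0
    dwell_mean_s: float = 0.8
    dwell_shape: float = 2.0
    heading_concentration: float = 50.0  # von Mises kappa
    walk_step_sd: float = 0.05  # cm/frame
    screen_attraction: float = 0.06  # OU pull per frame toward the target
    observer_offset_y: float = 0.5  # preferred distance behind the screen, cm
    demonstrator_visits_mean: float = 11.333
    demonstrator_visits_sd: float = 2.270
    visit_fill_fraction: float = 0.75  # share of the session spent feeding
    error_visit_prob: float = 0.005
    demonstrator_travel_y: float = 2.2  # travel depth, outside the dilation
    wall_flag_fraction: float = 0.15
    wall_episode_mean_s: float = 2.0
    likelihood_beta_params: tuple[float, float] = (2000.0, 1.0)
    dropout_prob: float = 0.001
    body_axis_cm: float = 0.45  # thorax-to-head distance
    occupancy_radius: float = 1.0
    # choice model (logit scale): innate bias toward yellow, facing-time
    # slopes per second toward the demonstrated colour
    innate_bias_logit: float = -1.2
    choice_betas: dict[str, float] = field(default_factory=lambda: {
        "occ_reward": 0.06, "unocc_reward": 0.03,
        "occ_nonreward": -0.04, "unocc_nonreward": -0.04,
    })
    n_choices_mean: float = 10.0
    n_choices_fixed: bool = False

    def __post_init__(self) -> None:
        w = self.attention_weights
        if set(w) != set(CATEGORIES):
            raise ConfigError("attention_weights must cover the four categories")
        if any(v < 0 for v in w.values()) or sum(w.values()) > 1.0 + 1e-9:
            raise ConfigError("attention weights must be >= 0 and sum to <= 1")
        if not 0 < self.visit_fill_fraction < 1:
            raise ConfigError("visit_fill_fraction must lie in (0, 1)")
        for name in ("fps", "dwell_mean_s", "dwell_shape",
                     "heading_concentration", "walk_step_sd",
                     "screen_attraction", "demonstrator_visits_mean",
                     "body_axis_cm", "occupancy_radius", "n_choices_mean"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        lo, hi = self.session_duration_s
        if not 0 < lo <= hi:
            raise ConfigError("session_duration_s must be a positive range")
        if not 0 <= self.wall_flag_fraction < 1:
            raise ConfigError("wall_flag_fraction must lie in [0, 1)")
        if not 0 <= self.error_visit_prob <= 1:
            raise ConfigError("error_visit_prob must be a probability")

    @property
    def off_weight(self) -> float:
        return max(0.0, 1.0 - sum(self.attention_weights.values()))


@dataclass
class GroundTruth:
    """What the generator actually did, frame by frame."""

    bee_id: str
    true_labels: np.ndarray  # per-frame FacingLabel codes (schedule-based)
    facing_seconds: dict[str, float]  # per category, over all frames
    session_duration_s: float
    demonstrator_visits: int
    attention_fractions: dict[str, float]  # this bee's scheduled fractions
    choice_params: dict[str, float]

    def true_fractions(self) -> dict[str, float]:
        n = len(self.true_labels)
        return {c: float(np.mean(self.true_labels == int(_CAT_TO_LABEL[c])))
                for c in CATEGORIES}


# ---------------------------------------------------------------------------
# demonstrator
# ---------------------------------------------------------------------------

def _demonstrator_path(rng: np.random.Generator, cfg: GeneratorConfig,
                       arena: ArenaSpec, n_frames: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Thorax path of the demonstrator over the session.

    Returns (x, y, n_visits).  Feeding dwell puts the thorax at the flower
    face (y ~ 0.4 cm); travel runs at ``demonstrator_travel_y``, outside
    the occupancy dilation.
    """
    rewarding = [f for f in arena.flowers if f.rewarding]
    nonrewarding = [f for f in arena.flowers if not f.rewarding]
    n_visits = max(1, int(round(rng.normal(cfg.demonstrator_visits_mean,
                                           cfg.demonstrator_visits_sd))))
    # which flower each visit lands on
    targets = []
    for _ in range(n_visits):
        if nonrewarding and rng.random() < cfg.error_visit_prob:
            targets.append(rng.choice(len(nonrewarding)) + len(rewarding))
        else:
            targets.append(rng.choice(len(rewarding)))
    flowers = rewarding + nonrewarding
    centers = np.array([f.center_x for f in flowers])

    # split the session into dwell (fill fraction) and travel/gap time
    dwell_frames = np.maximum(
        1, (rng.dirichlet(np.full(n_visits, 4.0))
            * cfg.visit_fill_fraction * n_frames).astype(int))
    gap_total = n_frames - int(dwell_frames.sum())
    gap_frames = np.maximum(
        1, (rng.dirichlet(np.full(n_visits + 1, 4.0)) * gap_total).astype(int))

    x = np.empty(n_frames)
    y = np.empty(n_frames)
    pos = 0
    feed_y = 0.4
    prev_x = centers[targets[0]]
    for v in range(n_visits):
        g = int(gap_frames[v]) if v < len(gap_frames) else 1
        g = min(g, n_frames - pos)
        tx = centers[targets[v]]
        if g > 0:
            # travel: retreat, slide along the feeding area, approach
            s = np.linspace(0.0, 1.0, g)
            x[pos:pos + g] = prev_x + (tx - prev_x) * s
            y[pos:pos + g] = feed_y + (cfg.demonstrator_travel_y - feed_y) * np.sin(
                np.pi * s)
            pos += g
        d = min(int(dwell_frames[v]), n_frames - pos)
        if d > 0:
            x[pos:pos + d] = tx + rng.normal(0.0, 0.08, d)
            y[pos:pos + d] = feed_y + rng.normal(0.0, 0.08, d)
            pos += d
        prev_x = tx
        if pos >= n_frames:
            break
    if pos < n_frames:  # final return toward the tunnel: retreat from the wall
        s = np.linspace(0.0, 1.0, n_frames - pos)
        x[pos:] = prev_x
        y[pos:] = feed_y + (cfg.demonstrator_travel_y - feed_y) * s
    np.clip(x, 0.3, arena.arena_width - 0.3, out=x)
    np.clip(y, 0.1, arena.screen_offset - 0.2, out=y)
    return x, y, n_visits


# ---------------------------------------------------------------------------
# attention schedule
# ---------------------------------------------------------------------------

def _occupancy_state(occ: np.ndarray, rewarding_mask: np.ndarray) -> np.ndarray:
    """Per-frame state code: -1 none, otherwise index of the occupied flower."""
    state = np.full(len(occ), -1, dtype=np.int64)
    rows, cols = np.nonzero(occ)
    state[rows] = cols
    del rewarding_mask
    return state


def _attention_schedule(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    arena: ArenaSpec,
    occ: np.ndarray,
    fractions: dict[str, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame attended flower index (-1 = off-target) and true labels.

    Category weights are conditioned on the realised occupancy state so
    that the expected realised fraction of each category matches the
    scheduled fraction; attention bouts never span an occupancy change.
    """
    n = len(occ)
    rewarding_mask = np.array([f.rewarding for f in arena.flowers])
    state = _occupancy_state(occ, rewarding_mask)

    # time shares in which the occupancy-dependent categories are realisable
    occ_any = state >= 0
    occ_reward_share = float(np.mean(occ_any & rewarding_mask[np.clip(state, 0, None)]
                                     & (state >= 0)))
    occ_nonrew_share = float(np.mean(occ_any & ~rewarding_mask[np.clip(state, 0, None)]
                                     & (state >= 0)))

    p_or = fractions["occ_reward"]
    p_ur = fractions["unocc_reward"]
    p_on = fractions["occ_nonreward"]
    p_un = fractions["unocc_nonreward"]
    w_or = min(p_or / occ_reward_share, 0.85) if occ_reward_share > 0 else 0.0
    w_on = min(p_on / occ_nonrew_share, 0.85) if occ_nonrew_share > 0 else 0.0

    # epoch boundaries where the occupancy state changes
    change = np.flatnonzero(np.diff(state)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))

    target = np.full(n, -1, dtype=np.int64)
    labels = np.full(n, int(FacingLabel.NO_FLOWER), dtype=np.int64)
    reward_idx = np.flatnonzero(rewarding_mask)
    nonreward_idx = np.flatnonzero(~rewarding_mask)
    centers = np.array([f.center_x for f in arena.flowers])
    dwell_scale = cfg.dwell_mean_s * cfg.fps / cfg.dwell_shape
    prev_x = arena.arena_width / 2.0  # where the bee last settled

    for s0, s1 in zip(starts, ends):
        st = state[s0]
        length = s1 - s0
        if st >= 0 and rewarding_mask[st]:
            cats = ("occ_reward", "unocc_reward", "unocc_nonreward", "off")
            w = np.array([w_or, p_ur, p_un, 0.0])
        elif st >= 0:
            cats = ("occ_nonreward", "unocc_reward", "unocc_nonreward", "off")
            w = np.array([w_on, p_ur, p_un, 0.0])
        else:
            cats = ("unocc_reward", "unocc_nonreward", "off")
            w = np.array([p_ur, p_un, 0.0])
        w[-1] = max(1.0 - w[:-1].sum(), 0.0)
        w = w / w.sum()

        # batch-draw enough bouts to cover the epoch
        n_draw = int(length / max(cfg.dwell_mean_s * cfg.fps, 1)) * 2 + 6
        while True:
            dwell = np.maximum(
                1, rng.gamma(cfg.dwell_shape, dwell_scale, n_draw).astype(int))
            if dwell.sum() >= length:
                break
            n_draw *= 2
        cat_idx = rng.choice(len(cats), size=n_draw, p=w)
        pos = s0
        for d, ci in zip(dwell, cat_idx):
            if pos >= s1:
                break
            d = min(int(d), s1 - pos)
            cat = cats[ci]
            if cat == "occ_reward" or cat == "occ_nonreward":
                fl = st
            elif cat == "unocc_reward":
                choices = reward_idx[reward_idx != st]
                # attend the eligible flower nearest the bee's last position
                fl = int(choices[np.argmin(np.abs(centers[choices] - prev_x))]
                         ) if len(choices) else -1
            elif cat == "unocc_nonreward":
                choices = nonreward_idx[nonreward_idx != st]
                fl = int(choices[np.argmin(np.abs(centers[choices] - prev_x))]
                         ) if len(choices) else -1
            else:
                fl = -1
            if fl < 0:
                cat = "off"
            else:
                prev_x = centers[fl]
            target[pos:pos + d] = fl
            labels[pos:pos + d] = int(_CAT_TO_LABEL[cat])
            pos += d
    return target, labels


# ---------------------------------------------------------------------------
# observer trajectory
# ---------------------------------------------------------------------------

def _ou_path(rng, anchor, k, step_sd, x0, lo, hi):
    """Discrete OU walk toward a per-frame anchor, folded into [lo, hi]."""
    n = len(anchor)
    u = k * anchor + step_sd * rng.standard_normal(n)
    path = lfilter([1.0], [1.0, -(1.0 - k)], u, zi=[(1.0 - k) * x0])[0]
    width = hi - lo
    z = np.mod(path - lo, 2 * width)
    return lo + np.where(z > width, 2 * width - z, z)


def _observer_tracks(rng, cfg: GeneratorConfig, arena: ArenaSpec,
                     target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thorax x/y and heading for the observer, given the attention targets."""
    n = len(target)
    centers = np.array([f.center_x for f in arena.flowers])
    y_pref = arena.screen_offset + cfg.observer_offset_y

    # anchors: attended flower's x while facing it; a wander point otherwise
    anchor_x = np.where(target >= 0, centers[np.clip(target, 0, None)], np.nan)
    anchor_y = np.where(target >= 0, y_pref, np.nan)
    off_runs = _runs(target < 0)
    for s0, s1 in off_runs:
        anchor_x[s0:s1] = rng.uniform(1.0, arena.arena_width - 1.0)
        anchor_y[s0:s1] = rng.uniform(arena.screen_offset + 0.6,
                                      arena.arena_depth - 0.6)
    margin = 0.3
    x = _ou_path(rng, anchor_x, cfg.screen_attraction, cfg.walk_step_sd,
                 anchor_x[0], margin, arena.arena_width - margin)
    y = _ou_path(rng, anchor_y, cfg.screen_attraction, cfg.walk_step_sd,
                 anchor_y[0], arena.screen_offset + margin,
                 arena.arena_depth - margin)

    # heading: at the flower's wall face while attending, else along a
    # per-bout wander direction away from the wall
    mu = np.empty(n)
    facing = target >= 0
    mu[facing] = np.arctan2(0.0 - y[facing],
                            centers[target[facing]] - x[facing])
    for s0, s1 in off_runs:
        mu[s0:s1] = rng.uniform(0.2, np.pi - 0.2)  # positive-y half plane
    heading = rng.vonmises(mu, cfg.heading_concentration)
    return x, y, heading


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) runs of True in a boolean array."""
    m = np.asarray(mask, bool)
    if not m.any():
        return []
    d = np.diff(m.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(len(m))
    return list(zip(starts, ends))


def _wall_flags(rng, cfg: GeneratorConfig, n: int) -> np.ndarray:
    """Alternating-renewal wall/ceiling episodes covering about the
    configured fraction of frames."""
    if cfg.wall_flag_fraction <= 0:
        return np.zeros(n, bool)
    mean_on = cfg.wall_episode_mean_s * cfg.fps
    mean_off = mean_on * (1 - cfg.wall_flag_fraction) / cfg.wall_flag_fraction
    flag = np.zeros(n, bool)
    pos = 0
    on = rng.random() < cfg.wall_flag_fraction
    while pos < n:
        mean = mean_on if on else mean_off
        d = max(1, int(rng.exponential(mean)))
        if on:
            flag[pos:pos + d] = True
        pos += d
        on = not on
    return flag


def _likelihoods(rng, cfg: GeneratorConfig, n: int) -> np.ndarray:
    a, b = cfg.likelihood_beta_params
    lk = rng.beta(a, b, size=(n, len(BODYPARTS)))
    drop = rng.random((n, len(BODYPARTS))) < cfg.dropout_prob
    lk[drop] = rng.uniform(0.0, 0.9, size=int(drop.sum()))
    return lk


def _make_track(animal_id, frames, x, y, heading, lk, fps, body_axis,
                flags=None, abdomen_axis=0.5):
    head_x = x + body_axis * np.cos(heading)
    head_y = y + body_axis * np.sin(heading)
    abd_x = x - abdomen_axis * np.cos(heading)
    abd_y = y - abdomen_axis * np.sin(heading)
    data = {
        "head": {"x": head_x, "y": head_y, "likelihood": lk[:, 0]},
        "thorax": {"x": x, "y": y, "likelihood": lk[:, 1]},
        "abdomen": {"x": abd_x, "y": abd_y, "likelihood": lk[:, 2]},
    }
    return PoseTrack(animal_id=animal_id, frame_index=frames, data=data,
                     fps=fps, excluded_flag=flags)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def simulate_session(
    cfg: GeneratorConfig,
    bee_id: str = "bee",
    arena: ArenaSpec | None = None,
    rng: np.random.Generator | None = None,
    attention_fractions: dict[str, float] | None = None,
    duration_s: float | None = None,
) -> tuple[PoseTrack, PoseTrack, GroundTruth]:
    """One synthetic observation session: observer + demonstrator tracks
    plus the ground truth that produced them.

    Per-bee attention fractions default to a Dirichlet draw around
    ``cfg.attention_weights`` (precision ``attention_concentration``), which
    is what makes facing times vary across bees.
    """
    arena = arena or default_arena()
    rng = rng or np.random.default_rng(cfg.seed)

    if duration_s is None:
        duration_s = float(rng.uniform(*cfg.session_duration_s))
    n = int(round(duration_s * cfg.fps))
    frames = np.arange(n, dtype=np.int64)

    if attention_fractions is None:
        base = np.array([cfg.attention_weights[c] for c in CATEGORIES]
                        + [cfg.off_weight])
        draw = rng.dirichlet(np.maximum(base, 1e-3) * cfg.attention_concentration)
        attention_fractions = dict(zip(CATEGORIES, draw[:-1]))
    else:
        attention_fractions = dict(attention_fractions)

    from .arena import occupancy_matrix  # local import avoids cycle at init

    demo_x, demo_y, n_visits = _demonstrator_path(rng, cfg, arena, n)
    occ = occupancy_matrix(demo_x, demo_y, np.ones(n, bool), arena,
                           cfg.occupancy_radius)
    target, true_labels = _attention_schedule(rng, cfg, arena, occ,
                                              attention_fractions)
    obs_x, obs_y, heading = _observer_tracks(rng, cfg, arena, target)

    lk_obs = _likelihoods(rng, cfg, n)
    lk_demo = _likelihoods(rng, cfg, n)
    flags = _wall_flags(rng, cfg, n)

    observer = _make_track(f"{bee_id}_observer", frames, obs_x, obs_y, heading,
                           lk_obs, cfg.fps, cfg.body_axis_cm, flags=flags)
    demo_heading = np.full(n, -np.pi / 2)  # feeding posture: facing the wall
    demonstrator = _make_track(f"{bee_id}_demonstrator", frames, demo_x, demo_y,
                               demo_heading, lk_demo, cfg.fps, cfg.body_axis_cm)

    facing_seconds = {
        c: float(np.sum(true_labels == int(_CAT_TO_LABEL[c]))) / cfg.fps
        for c in CATEGORIES
    }
    truth = GroundTruth(
        bee_id=bee_id,
        true_labels=true_labels,
        facing_seconds=facing_seconds,
        session_duration_s=n / cfg.fps,
        demonstrator_visits=n_visits,
        attention_fractions=attention_fractions,
        choice_params={"innate_bias_logit": cfg.innate_bias_logit,
                       **{f"beta_{c}": cfg.choice_betas[c] for c in CATEGORIES}},
    )
    return observer, demonstrator, truth


def simulate_choice_counts(
    facing_seconds: dict[str, float],
    group: str,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[int, int, str]:
    """(n_choices, n_yellow, first_choice) from the logistic choice model.

    The linear predictor on the yellow-choice logit is the innate bias plus
    the facing-time effects signed toward the group's demonstrated colour
    (+ for Yellow, - for Blue, absent for Control).
    """
    eta = cfg.innate_bias_logit
    sign = {"Yellow": 1.0, "Blue": -1.0}.get(group, 0.0)
    if sign != 0.0:
        eta += sign * sum(cfg.choice_betas[c] * facing_seconds.get(f"t_{c}",
                          facing_seconds.get(c, 0.0)) for c in CATEGORIES)
    p_yellow = 1.0 / (1.0 + np.exp(-eta))
    if cfg.n_choices_fixed:
        n_choices = int(round(cfg.n_choices_mean))
    else:
        n_choices = max(1, int(rng.poisson(cfg.n_choices_mean)))
    n_yellow = int(rng.binomial(n_choices, p_yellow))
    first = "yellow" if rng.random() < p_yellow else "blue"
    return n_choices, n_yellow, first


def simulate_choices(
    truths: list[GroundTruth],
    group: str,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    colony_ids: list[str] | None = None,
):
    """ChoiceRecords for a set of sessions' ground truths (one group)."""
    from .stats import ChoiceRecord

    records = []
    for i, truth in enumerate(truths):
        n_choices, n_yellow, first = simulate_choice_counts(
            truth.facing_seconds, group, cfg, rng)
        records.append(ChoiceRecord(
            bee_id=truth.bee_id, group=group,
            colony_id=colony_ids[i] if colony_ids else "C1",
            n_choices=n_choices, n_yellow=n_yellow, first_choice=first))
    return records


def simulate_facing_summaries(
    cfg: GeneratorConfig,
    n_bees: int,
    rng: np.random.Generator,
    valid_fraction: float = 0.85,
) -> list[dict[str, float]]:
    """Fast summary-level draws of per-bee facing seconds.

    Samples each bee's session duration and attention fractions from the
    same distributions the frame-level generator uses, skipping trajectory
    synthesis; used by the statistical recovery simulations where thousands
    of replicate datasets are needed.
    """
    base = np.array([cfg.attention_weights[c] for c in CATEGORIES]
                    + [cfg.off_weight])
    out = []
    for _ in range(n_bees):
        duration = rng.uniform(*cfg.session_duration_s)
        frac = rng.dirichlet(np.maximum(base, 1e-3) * cfg.attention_concentration)
        seconds = frac[:-1] * duration * valid_fraction
        out.append({f"t_{c}": float(s) for c, s in zip(CATEGORIES, seconds)}
                   | {"session_duration": float(duration)})
    return out


def make_fixture_suite(out_dir: str | Path, seed: int = 0,
                       n_bees_per_group: int = 6,
                       session_duration_s: float = 30.0,
                       cfg: GeneratorConfig | None = None) -> dict[str, Path]:
    """Write a small end-to-end dataset in the pipeline's external formats.

    Produces, under ``out_dir``: one pose-track CSV per observer session, an
    arena YAML (with calibration), a choices CSV covering the Blue, Yellow
    and Control groups, and a ground-truth JSON.  Regenerating with the same
    seed reproduces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = cfg or GeneratorConfig(seed=seed)
    cfg = replace(cfg, seed=seed,
                  session_duration_s=(session_duration_s, session_duration_s))
    rng = np.random.default_rng(seed)
    calibration = Calibration(px_per_cm=50.0, origin_x_px=40.0, origin_y_px=60.0)

    tracks_dir = out_dir / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    choice_rows = []
    truth_json: dict[str, dict] = {}
    colonies = ["C1", "C2"]
    paths: dict[str, Path] = {}

    for group in ("Blue", "Yellow", "Control"):
        arena = default_arena(demonstrated_colour=group.lower()
                              if group != "Control" else "blue")
        for i in range(n_bees_per_group):
            bee_id = f"{group.lower()}_{i:02d}"
            colony = colonies[i % len(colonies)]
            if group == "Control":
                facing = {f"t_{c}": 0.0 for c in CATEGORIES}
                truth_json[bee_id] = {"group": group, "colony": colony,
                                      "facing_seconds": facing}
            else:
                observer, demonstrator, truth = simulate_session(
                    cfg, bee_id=bee_id, arena=arena, rng=rng)
                track_path = tracks_dir / f"{bee_id}.csv"
                write_pose_tracks(track_path,
                                  {"observer": observer,
                                   "demonstrator": demonstrator},
                                  calibration)
                facing = {f"t_{c}": truth.facing_seconds[c] for c in CATEGORIES}
                truth_json[bee_id] = {
                    "group": group, "colony": colony,
                    "facing_seconds": facing,
                    "attention_fractions": truth.attention_fractions,
                    "demonstrator_visits": truth.demonstrator_visits,
                }
            n_choices, n_yellow, first = simulate_choice_counts(
                facing, group, cfg, rng)
            choice_rows.append({
                "bee_id": bee_id, "group": group, "colony_id": colony,
                "n_choices": n_choices, "n_yellow": n_yellow,
                "first_choice": first,
            })

    choices_path = out_dir / "choices.csv"
    pd.DataFrame(choice_rows).to_csv(choices_path, index=False)
    arena_path = out_dir / "arena.yaml"
    arena_yaml = {
        "arena": {
            "arena_width": 15.2, "arena_depth": 12.8, "screen_offset": 2.8,
            "flower_width": 2.4, "flower_depth": 0.8, "flower_gap": 1.6,
            "fps": cfg.fps,
            "flowers": [
                {"flower_id": f.flower_id, "center_x": float(f.center_x),
                 "colour": f.colour}
                for f in default_arena().flowers
            ],
        },
        "calibration": {"px_per_cm": 50.0, "origin_x_px": 40.0,
                        "origin_y_px": 60.0},
    }
    arena_path.write_text(yaml.safe_dump(arena_yaml, sort_keys=False))
    truth_path = out_dir / "ground_truth.json"
    truth_path.write_text(json.dumps(
        {"seed": seed, "config": {"innate_bias_logit": cfg.innate_bias_logit,
                                  "choice_betas": cfg.choice_betas},
         "bees": truth_json}, indent=1, sort_keys=True))
    paths.update({"tracks": tracks_dir, "choices": choices_path,
                  "arena": arena_path, "ground_truth": truth_path})
    return paths
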