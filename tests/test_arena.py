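"""Geometry: arena construction, headings, occupancy, facing classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from beegaze.arena import (
    ArenaSpec,
    DegeneratePoseError,
    FacingLabel,
    FlowerSpec,
    OccupancyFrame,
    Pose2D,
    PoseOutsideChamberError,
    classify_facing,
    classify_frames,
    compute_heading,
    compute_occupancy,
    default_arena,
    facing_flower_index,
    normalize_angle,
    occupancy_matrix,
)


class TestDefaultArena:
    def test_flower_centres_from_printed_dimensions(self, arena):
        # 4 x 2.4 + 3 x 1.6 = 14.4 cm array centred on the 15.2 cm wall
        assert [f.center_x for f in arena.flowers] == pytest.approx(
            [1.6, 5.6, 9.6, 13.6])

    def test_frame_rate_and_screen(self, arena):
        assert arena.fps == 100
        assert arena.screen_offset == 2.8
        assert arena.arena_depth == 12.8

    def test_array_fits_on_wall(self, arena):
        ivals = arena.flower_intervals
        assert ivals.min() >= 0 and ivals.max() <= arena.arena_width
        span = ivals.max() - ivals.min()
        assert span == pytest.approx(14.4)

    def test_reward_roles_follow_demonstrated_colour(self):
        blue = default_arena("blue")
        yellow = default_arena("yellow")
        assert [f.rewarding for f in blue.flowers] == [True, False, False, True]
        assert [f.rewarding for f in yellow.flowers] == [False, True, True, False]

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ArenaSpec(screen_offset=13.0)  # beyond depth
        with pytest.raises(ValueError):
            ArenaSpec(flowers=(
                FlowerSpec("a", 2.0, "blue", True),
                FlowerSpec("b", 3.0, "yellow", False),  # overlaps a
            ))


class TestComputeHeading:
    @pytest.mark.parametrize("thorax,head,expected", [
        ((0, 0), (1, 0), 0.0),
        ((0, 0), (0, -2), -math.pi / 2),
        ((3, 3), (2, 4), 3 * math.pi / 4),
        ((1, 1), (0, 0), -3 * math.pi / 4),
    ])
    def test_examples(self, thorax, head, expected):
        assert compute_heading(thorax, head) == pytest.approx(expected)

    def test_degenerate_pose_raises(self):
        with pytest.raises(DegeneratePoseError):
            compute_heading((0.0, 0.0), (0.01, 0.0))

    @given(st.floats(-50, 50), st.floats(-50, 50),
           st.floats(0.1, 10), st.floats(-10, 10))
    @settings(max_examples=200, deadline=None)
    def test_heading_in_range_and_matches_atan2(self, x, y, r, theta):
        head = (x + r * math.cos(theta), y + r * math.sin(theta))
        h = compute_heading((x, y), head)
        assert -math.pi < h <= math.pi
        assert math.isclose(math.cos(h), math.cos(theta), abs_tol=1e-9)
        assert math.isclose(math.sin(h), math.sin(theta), abs_tol=1e-9)

    @given(st.floats(-100, 100))
    @settings(max_examples=200, deadline=None)
    def test_normalize_angle_wraps_into_half_open_interval(self, theta):
        w = normalize_angle(theta)
        assert -math.pi < w <= math.pi
        assert math.isclose(math.cos(w), math.cos(theta), abs_tol=1e-9)


def _occupancy_oracle(px, py, arena, radius):
    """Brute-force dilated-rectangle containment with nearest-centre tie-break."""
    inside = []
    for f in arena.flowers:
        lo, hi = f.interval(arena.flower_width)
        inside.append(lo - radius <= px <= hi + radius
                      and -radius <= py <= arena.flower_depth + radius)
    if sum(inside) > 1:
        best = min((abs(px - f.center_x), i)
                   for i, f in enumerate(arena.flowers) if inside[i])[1]
        inside = [i == best for i in range(len(inside))]
    return tuple(inside)


class TestOccupancy:
    def test_demonstrator_at_flower_centre(self, arena):
        occ = compute_occupancy(Pose2D(5.6, 0.4, 0.0), arena)
        assert occ.occupied == (False, True, False, False)

    def test_absent_demonstrator_all_unoccupied(self, arena):
        occ = compute_occupancy(None, arena)
        assert occ.occupied == (False,) * 4

    def test_travel_depth_outside_dilation(self, arena):
        occ = compute_occupancy(Pose2D(5.6, 2.2, 0.0), arena)
        assert not any(occ.occupied)

    def test_matches_brute_force_containment(self, arena):
        rng = np.random.default_rng(0)
        xs = rng.uniform(-0.5, arena.arena_width + 0.5, 500)
        ys = rng.uniform(-0.5, arena.screen_offset, 500)
        for px, py in zip(xs, ys):
            occ = compute_occupancy((px, py), arena)
            assert occ.occupied == _occupancy_oracle(px, py, arena, 1.0)

    def test_at_most_one_flower_occupied_even_mid_gap(self, arena):
        # the gap (1.6 cm) is smaller than twice the radius: tie-break applies
        gap_mid = (1.6 + 5.6) / 2
        occ = compute_occupancy((gap_mid, 0.4), arena)
        assert sum(occ.occupied) == 1

    def test_vectorised_matches_scalar(self, arena):
        rng = np.random.default_rng(1)
        xs = rng.uniform(0, arena.arena_width, 300)
        ys = rng.uniform(0, arena.screen_offset, 300)
        mat = occupancy_matrix(xs, ys, np.ones(300, bool), arena, 1.0)
        for i in range(300):
            assert tuple(mat[i]) == compute_occupancy((xs[i], ys[i]), arena).occupied

    def test_occupancy_frame_rejects_multiple(self):
        with pytest.raises(ValueError):
            OccupancyFrame(0, (True, True, False, False))


def _ray_oracle(x, y, heading, arena, n_samples=4000):
    """Densely sample points along the ray and test flower-interval hits."""
    ts = np.linspace(1e-6, 40.0, n_samples)
    px = x + ts * math.cos(heading)
    py = y + ts * math.sin(heading)
    near_wall = np.abs(py) <= 0.02
    for f in arena.flowers:
        lo, hi = f.interval(arena.flower_width)
        if np.any(near_wall & (px >= lo) & (px <= hi)):
            return f
    return None


class TestClassifyFacing:
    def _occ(self, arena, occupied_idx=None):
        occ = [False] * len(arena.flowers)
        if occupied_idx is not None:
            occ[occupied_idx] = True
        return OccupancyFrame(0, tuple(occ))

    def test_perpendicular_ray_onto_occupied_rewarding(self, arena):
        lbl = classify_facing(Pose2D(1.6, 6.0, -math.pi / 2),
                              self._occ(arena, 0), arena)
        assert lbl is FacingLabel.OCC_REWARD

    def test_facing_away_from_wall(self, arena):
        lbl = classify_facing(Pose2D(5.6, 6.0, math.pi / 2),
                              self._occ(arena), arena)
        assert lbl is FacingLabel.NO_FLOWER

    def test_unoccupied_nonrewarding(self, arena):
        lbl = classify_facing(Pose2D(5.6, 6.0, -math.pi / 2),
                              self._occ(arena), arena)
        assert lbl is FacingLabel.UNOCC_NONREWARD

    def test_interval_endpoint_counts_as_hit(self, arena):
        # aim exactly at the left edge of flower 0 (x = 0.4) from right above
        lbl = classify_facing(Pose2D(0.4, 6.0, -math.pi / 2),
                              self._occ(arena), arena)
        assert lbl is FacingLabel.UNOCC_REWARD

    def test_observer_in_feeding_area_is_an_error(self, arena):
        with pytest.raises(PoseOutsideChamberError):
            classify_facing(Pose2D(5.0, 1.0, 0.0), self._occ(arena), arena)

    def test_rotation_by_pi_yields_no_flower(self, arena):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(200):
            pose = Pose2D(rng.uniform(0, 15.2), rng.uniform(3.0, 12.5),
                          rng.uniform(-math.pi, math.pi))
            lbl = classify_facing(pose, self._occ(arena), arena)
            if lbl in (FacingLabel.UNOCC_REWARD, FacingLabel.UNOCC_NONREWARD):
                hits += 1
                flipped = Pose2D(pose.x, pose.y, pose.heading + math.pi)
                assert classify_facing(flipped, self._occ(arena), arena) \
                    is FacingLabel.NO_FLOWER
        assert hits > 10  # the property was actually exercised

    def test_agrees_with_dense_sampling_oracle(self, arena):
        rng = np.random.default_rng(4)
        n = 2000
        xs = rng.uniform(0, arena.arena_width, n)
        ys = rng.uniform(3.0, arena.arena_depth - 0.2, n)
        hs = rng.uniform(-math.pi, math.pi, n)
        idx = facing_flower_index(xs, ys, hs, arena)
        mismatches = 0
        for i in range(n):
            oracle = _ray_oracle(xs[i], ys[i], hs[i], arena)
            got = None if idx[i] < 0 else arena.flowers[idx[i]]
            if oracle is not got:
                mismatches += 1
        assert mismatches / n <= 0.001

    def test_translation_invariance_along_wall(self):
        rng = np.random.default_rng(5)
        base = default_arena()
        dx = 0.35
        shifted = base.with_flowers([
            FlowerSpec(f.flower_id, f.center_x + dx, f.colour, f.rewarding)
            for f in base.flowers
        ])
        xs = rng.uniform(1, 13, 500)
        ys = rng.uniform(3.0, 12.5, 500)
        hs = rng.uniform(-math.pi, math.pi, 500)
        a = facing_flower_index(xs, ys, hs, base)
        b = facing_flower_index(xs + dx, ys, hs, shifted)
        assert np.array_equal(a, b)

    def test_no_multi_hit_possible(self, arena):
        # disjoint closed intervals on a line: one ray, at most one flower
        rng = np.random.default_rng(6)
        xs = rng.uniform(0, 15.2, 2000)
        ys = rng.uniform(3.0, 12.5, 2000)
        hs = rng.uniform(-math.pi, 0, 2000)  # all toward the wall
        sin_h = np.sin(hs)
        x_star = xs + ys * np.cos(hs) / (-sin_h)
        ivals = arena.flower_intervals
        n_hits = ((x_star[:, None] >= ivals[None, :, 0])
                  & (x_star[:, None] <= ivals[None, :, 1])).sum(axis=1)
        assert n_hits.max() <= 1

    def test_partition_every_frame_gets_one_label(self, arena):
        rng = np.random.default_rng(7)
        n = 1000
        labels = classify_frames(
            rng.uniform(0, 15.2, n), rng.uniform(3.0, 12.5, n),
            rng.uniform(-math.pi, math.pi, n),
            valid=rng.random(n) < 0.8,
            occupied=np.zeros((n, 4), bool), arena=arena)
        counts = np.bincount(labels, minlength=6)
        assert counts.sum() == n
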