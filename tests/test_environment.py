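"""Arena geometry, trajectory, visibility and Poisson drive."""

import numpy as np
import pytest

from placesim.config import ArenaConfig, ObjectConfig, TrajectoryConfig
from placesim.environment import (Arena, TrajectoryState, VisualField,
                                  initial_trajectory_state,
                                  poisson_spike_train, presynaptic_rates,
                                  rotate_arena, step_trajectory,
                                  visible_features)


@pytest.fixture
def arena():
    return Arena.from_config(ArenaConfig(objects=[
        ObjectConfig("red", 0.85, 0.5, 0.06, 0.5, 7),
        ObjectConfig("blue", 0.15, 0.5, 0.06, 0.5, 7),
    ]))


@pytest.fixture
def vf():
    return VisualField(fov=90.0, max_range=0.8, full_resolution_fraction=0.45)


class TestTrajectory:
    def test_zero_speed_stays_put(self, arena):
        s = TrajectoryState(np.array([0.5, 0.5]), 0.0, speed=0.0)
        s2 = step_trajectory(s, 0.1, np.random.default_rng(0), arena)
        np.testing.assert_allclose(s2.position, [0.5, 0.5])

    def test_same_seed_same_path(self, arena):
        cfg = TrajectoryConfig()
        paths = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            s = initial_trajectory_state(cfg, rng, arena)
            xs = []
            for _ in range(200):
                s = step_trajectory(s, 0.1, rng, arena)
                xs.append(s.position.copy())
            paths.append(np.array(xs))
        np.testing.assert_array_equal(paths[0], paths[1])

    def test_reflective_walls_keep_agent_inside(self, arena):
        rng = np.random.default_rng(3)
        s = TrajectoryState(np.array([0.95, 0.95]), 45.0, speed=0.5)
        for _ in range(2000):
            s = step_trajectory(s, 0.1, rng, arena)
            assert 0.0 <= s.position[0] <= arena.side_length
            assert 0.0 <= s.position[1] <= arena.side_length
            assert 0.0 <= s.heading < 360.0

    def test_occupancy_covers_most_of_the_arena(self, arena):
        rng = np.random.default_rng(7)
        s = initial_trajectory_state(TrajectoryConfig(), rng, arena)
        pos = np.empty((10000, 2))
        for i in range(10000):
            s = step_trajectory(s, 0.1, rng, arena)
            pos[i] = s.position
        H, _, _ = np.histogram2d(pos[:, 0], pos[:, 1],
                                 bins=10, range=[[0, 1], [0, 1]])
        assert (H > 0).mean() > 0.8


class TestVisibility:
    def test_facing_away_sees_nothing(self, arena, vf):
        s = TrajectoryState(np.array([0.5, 0.5]), 180.0, speed=0.1)
        visible = visible_features(s, arena, vf)
        assert not any(f.startswith("red") for f in visible)

    def test_adjacent_and_facing_sees_all_features(self, arena, vf):
        # close enough for full resolution, far enough that the whole bar
        # fits inside the 90-degree field of view
        s = TrajectoryState(np.array([0.55, 0.5]), 0.0, speed=0.1)
        visible = visible_features(s, arena, vf)
        assert {f"red:{k}" for k in range(7)} <= visible

    def test_out_of_range_is_invisible(self, arena):
        vf_short = VisualField(fov=90.0, max_range=0.2)
        s = TrajectoryState(np.array([0.3, 0.5]), 0.0, speed=0.1)
        assert visible_features(s, arena, vf_short) == set()

    def test_rigid_rotation_invariance(self, arena, vf):
        s = TrajectoryState(np.array([0.55, 0.5]), 0.0, speed=0.1)
        before = visible_features(s, arena, vf)
        rot = rotate_arena(arena, 137.0)
        a = np.radians(137.0)
        c, si = np.cos(a), np.sin(a)
        p = s.position - arena.center
        s2 = TrajectoryState(arena.center + np.array(
            [c * p[0] - si * p[1], si * p[0] + c * p[1]]),
            (s.heading + 137.0) % 360.0, speed=0.1)
        after = visible_features(s2, rot, vf)
        assert before == after

    def test_resolution_decays_with_distance(self, vf):
        assert vf.resolution_decay(0.0) == 1.0
        assert vf.resolution_decay(0.2) == 1.0      # inside full-res zone
        d = [vf.resolution_decay(r) for r in (0.4, 0.6, 0.79)]
        assert all(x > y for x, y in zip(d, d[1:]))
        assert vf.resolution_decay(0.85) == 0.0

    def test_invalid_fov_rejected(self):
        with pytest.raises(ValueError):
            VisualField(fov=0.0)


class TestRates:
    MAP = {f"red:{k}": f"syn{k}" for k in range(7)} | \
          {f"blue:{k}": f"syn{7 + k}" for k in range(7)}

    def test_nothing_visible_all_background(self):
        rates = presynaptic_rates(set(), self.MAP)
        assert set(rates.values()) == {3.0}

    def test_visible_object_at_cue_rate_others_background(self):
        visible = {f"red:{k}" for k in range(7)}
        rates = presynaptic_rates(visible, self.MAP)
        assert all(rates[f"syn{k}"] == 80.0 for k in range(7))
        assert all(rates[f"syn{7 + k}"] == 3.0 for k in range(7))

    def test_all_visible_all_cue_rate(self):
        rates = presynaptic_rates(set(self.MAP), self.MAP)
        assert set(rates.values()) == {80.0}

    def test_non_bijective_map_rejected(self):
        bad = {"red:0": "syn0", "red:1": "syn0"}
        with pytest.raises(ValueError):
            presynaptic_rates(set(), bad)


class TestPoisson:
    def test_zero_rate_gives_no_spikes(self):
        rng = np.random.default_rng(0)
        assert poisson_spike_train(lambda t: 0.0, 0.0, 1e5, rng).size == 0

    def test_count_matches_cue_rate(self):
        rng = np.random.default_rng(1)
        spikes = poisson_spike_train(lambda t: 80.0, 0.0, 100_000.0, rng)
        assert abs(spikes.size - 8000) < 4 * np.sqrt(8000)

    def test_background_rate_recovered(self):
        rng = np.random.default_rng(2)
        spikes = poisson_spike_train(lambda t: 3.0, 0.0, 1_000_000.0, rng)
        rate = spikes.size / 1000.0
        se = np.sqrt(3.0 / 1000.0)
        assert abs(rate - 3.0) < 3 * se

    def test_dispersion_is_poisson_like(self):
        rng = np.random.default_rng(3)
        for rate in (3.0, 80.0):
            spikes = poisson_spike_train(lambda t: rate, 0.0, 200_000.0, rng)
            counts = np.histogram(spikes, bins=200,
                                  range=(0, 200_000.0))[0]
            fano = counts.var() / counts.mean()
            assert 0.8 < fano < 1.25

    def test_sorted_within_window(self):
        rng = np.random.default_rng(4)
        s = poisson_spike_train(lambda t: 50.0, 500.0, 2500.0, rng)
        assert np.all(np.diff(s) >= 0)
        assert s.min() >= 500.0 and s.max() < 2500.0

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            poisson_spike_train(lambda t: 1.0, 10.0, 10.0,
                                np.random.default_rng(0))


class TestRotateArena:
    def test_identity_rotations(self, arena):
        r0 = rotate_arena(arena, 0.0)
        r360 = rotate_arena(arena, 360.0)
        for rot in (r0, r360):
            for a, b in zip(arena.objects, rot.objects):
                np.testing.assert_allclose(rot.object_center(b),
                                           arena.object_center(a),
                                           atol=1e-12)

    def test_two_quarter_turns_equal_half_turn(self, arena):
        twice = rotate_arena(rotate_arena(arena, 90.0), 90.0)
        once = rotate_arena(arena, 180.0)
        for a, b in zip(twice.objects, once.objects):
            np.testing.assert_allclose(twice.object_center(a),
                                       once.object_center(b), atol=1e-12)

    def test_feature_mapping_preserved(self, arena):
        rot = rotate_arena(arena, 90.0)
        assert rot.all_feature_ids() == arena.all_feature_ids()

    def test_object_outside_arena_rejected(self):
        with pytest.raises(ValueError):
            Arena.from_config(ArenaConfig(objects=[
                ObjectConfig("x", 1.5, 0.5, 0.1, 0.1, 7)]))
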