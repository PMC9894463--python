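"""Behavioral rules: perception, the six forces, speed cap, integration."""

import math

import numpy as np
import pytest

from schoolfeed.behavior import (WALL_EPS, alignment_force,
                                 boundary_force, cap_speed, cohesion_force,
                                 feed_force, integrate_step, neighbors_in_view,
                                 random_force, separation_force, total_force)
from schoolfeed.config import BehaviorWeights, Tank
from schoolfeed.scenarios import make_fish, make_school

W = BehaviorWeights()
TL = 0.14082  # ~allometric total length of a 38.53 g fish, meters


def perceive(focal, school, **kw):
    return neighbors_in_view(focal, school, **kw)


class TestPerception:
    def test_sphere_radius_is_two_body_lengths(self):
        focal = make_fish(0, (0, 0, 0.75), (0.1, 0, 0))
        near = make_fish(1, (1.9 * focal.total_length, 0, 0.75))
        far = make_fish(2, (0, 2.1 * focal.total_length, 0.75))
        p = perceive(focal, [focal, near, far])
        assert p.neighbor_ids == [1]
        assert p.nearest_neighbor_id == 1

    def test_rear_dead_cone(self):
        # moving along +x; directly behind is blind, 45 degrees off is not
        focal = make_fish(0, (0, 0, 0.75), (0.1, 0, 0))
        tl = focal.total_length
        behind = make_fish(1, (-1.0 * tl, 0, 0.75))
        off45 = make_fish(2, (-tl / math.sqrt(2), tl / math.sqrt(2), 0.75))
        p = perceive(focal, [focal, behind, off45])
        assert 1 not in p.neighbor_ids
        assert 2 in p.neighbor_ids

    def test_dead_cone_half_angle_brute_force(self):
        # sweep directions; exclusion iff angle from the rear axis < 30 deg
        focal = make_fish(0, (0, 0, 0.75), (0.2, 0, 0))
        tl = focal.total_length
        for theta_deg in range(0, 181, 5):
            if theta_deg == 30:
                continue  # boundary of the cone, ambiguous by convention
            th = math.radians(theta_deg)
            # position at angle theta from -v (the rear axis), distance 1 TL
            pos = (-tl * math.cos(th), tl * math.sin(th), 0.75)
            other = make_fish(1, pos)
            p = perceive(focal, [focal, other])
            expected_excluded = theta_deg < 30
            assert (1 not in p.neighbor_ids) == expected_excluded, theta_deg

    def test_zero_speed_has_no_dead_cone(self):
        focal = make_fish(0, (0, 0, 0.75), (0, 0, 0))
        behind = make_fish(1, (-0.5 * focal.total_length, 0, 0.75))
        p = perceive(focal, [focal, behind])
        assert 1 in p.neighbor_ids


class TestRuleForces:
    def test_separation_unit_example(self):
        focal = make_fish(0, (0, 0, 1))
        other = make_fish(1, (1, 0, 1))
        # force perception: place the neighbor in view
        focal.total_length = 1.0
        p = perceive(focal, [focal, other])
        f = separation_force(focal, p, [focal, other], 0.6)
        np.testing.assert_allclose(f, [-0.6, 0, 0], atol=1e-15)

    def test_separation_absent_without_neighbors(self):
        focal = make_fish(0)
        p = perceive(focal, [focal])
        assert np.all(separation_force(focal, p, [focal], 0.6) == 0)

    def test_separation_uses_only_the_nearest(self):
        focal = make_fish(0, (0, 0, 0.75), total_length=2.0)
        near = make_fish(1, (0.1, 0, 0.75))
        far = make_fish(2, (0, 0.2, 0.75))
        p = perceive(focal, [focal, near, far])
        f = separation_force(focal, p, [focal, near, far], 0.6)
        np.testing.assert_allclose(f, [-0.6, 0, 0], atol=1e-15)

    def test_cohesion_toward_symmetric_centroid(self):
        focal = make_fish(0, (0, 1, 0.75), total_length=3.0)
        school = [focal, make_fish(1, (1, 0, 0.75)),
                  make_fish(2, (-1, 0, 0.75))]
        p = perceive(focal, school)
        f = cohesion_force(focal, p, school, 0.4)
        np.testing.assert_allclose(f, [0, -0.4, 0], atol=1e-15)

    def test_cohesion_brute_force_random_neighbors(self, rng):
        focal = make_fish(0, (0, 0, 0.75), total_length=50.0)
        others = [make_fish(i + 1, rng.uniform(-1, 1, 3) + [0, 0, 0.75])
                  for i in range(5)]
        school = [focal] + others
        p = perceive(focal, school)
        f = cohesion_force(focal, p, school, 0.4)
        centroid = np.mean([o.position for o in others], axis=0)
        d = centroid - focal.position
        np.testing.assert_allclose(f, 0.4 * d / np.linalg.norm(d), rtol=1e-12)

    def test_alignment_zero_when_aligned(self):
        focal = make_fish(0, (0, 0, 0.75), (0.2, 0, 0), total_length=3.0)
        other = make_fish(1, (0.5, 0, 0.75), (0.2, 0, 0))
        p = perceive(focal, [focal, other])
        f = alignment_force(focal, p, [focal, other], 0.4)
        assert np.all(f == 0)

    def test_alignment_unit_example(self):
        focal = make_fish(0, (0, 0, 0.75), (0, 0, 0), total_length=3.0)
        other = make_fish(1, (0.5, 0, 0.75), (0.2, 0, 0))
        p = perceive(focal, [focal, other])
        f = alignment_force(focal, p, [focal, other], 0.4)
        np.testing.assert_allclose(f, [0.4, 0, 0], atol=1e-15)

    def test_boundary_wall_repulsion(self):
        tank = Tank(1.5, 1.5)
        fish = make_fish(0, (1.45, 0, 0.75), total_length=0.14)
        f = boundary_force(fish, tank, 1.0)
        np.testing.assert_allclose(f, [-1.0, 0, 0], atol=1e-12)

    def test_boundary_silent_at_center(self):
        tank = Tank(1.5, 1.5)
        fish = make_fish(0, (0, 0, 0.75), total_length=0.14)
        assert np.all(boundary_force(fish, tank, 1.0) == 0)

    def test_boundary_picks_nearest_of_three_candidates(self, rng):
        tank = Tank(1.5, 1.5)
        for _ in range(50):
            r = rng.uniform(1.2, 1.499)
            th = rng.uniform(0, 2 * np.pi)
            z = rng.uniform(0.001, 0.3)
            pos = np.array([r * np.cos(th), r * np.sin(th), z])
            fish = make_fish(0, pos, total_length=0.2)
            f = boundary_force(fish, tank, 1.0)
            dists = {"wall": tank.radius - r, "bottom": z,
                     "surface": tank.depth - z}
            in_view = {k: v for k, v in dists.items() if v <= 0.4}
            if not in_view:
                assert np.all(f == 0)
                continue
            nearest = min(in_view, key=in_view.get)
            if nearest == "wall":
                expected = -pos / np.linalg.norm(pos[:2])
                expected[2] = 0.0
                np.testing.assert_allclose(f, expected, atol=1e-12)
            elif nearest == "bottom":
                np.testing.assert_allclose(f, [0, 0, 1.0], atol=1e-12)
            else:
                np.testing.assert_allclose(f, [0, 0, -1.0], atol=1e-12)

    def test_feed_attraction_by_mode(self):
        fish = make_fish(0, (0, 0, 0), mode="feeding")
        f = feed_force(fish, np.array([0, 0, 1.0]), 3.0)
        np.testing.assert_allclose(f, [0, 0, 3.0], atol=1e-15)
        assert np.all(feed_force(fish, np.array([0, 0, 1.0]), 0.0) == 0)

    def test_feed_targets_nearest_pellet_regardless_of_view(self):
        # pellet behind the fish (outside the field of view) still detected
        fish = make_fish(0, (0, 0, 0.75), (0.1, 0, 0), mode="feeding")
        pellets = np.array([[-0.3, 0, 0.75], [0.5, 0, 0.75]])
        p = neighbors_in_view(fish, [fish], pellet_positions=pellets)
        np.testing.assert_allclose(p.nearest_pellet_position, pellets[0])

    def test_random_force_magnitude_and_reproducibility(self):
        f = random_force(np.random.default_rng(5), 0.2)
        assert np.linalg.norm(f) == pytest.approx(0.2, rel=1e-12)
        again = random_force(np.random.default_rng(5), 0.2)
        np.testing.assert_array_equal(f, again)

    def test_random_direction_has_no_mean_bias(self):
        # the cube-normalized scheme is anisotropic (corners of the cube are
        # over-represented) but must have zero mean direction
        rng = np.random.default_rng(0)
        n = 20000
        draws = np.array([random_force(rng, 1.0) for _ in range(n)])
        mean = draws.mean(axis=0)
        assert np.linalg.norm(mean) < 4.0 / math.sqrt(n)

    def test_total_force_is_sum_of_components(self, rng):
        tank = Tank(1.5, 1.5)
        school = make_school([(1.3, 0, 0.2), (1.35, 0.05, 0.25),
                              (1.25, -0.05, 0.18)], mass=38.53)
        for f in school:
            f.velocity = rng.uniform(-0.1, 0.1, 3)
            f.mode = "feeding"
        pellets = np.array([[0.5, 0.5, 1.0], [0.2, 0.1, 1.2]])
        focal = school[0]
        unit = np.array([1.0, 0, 0])
        p = neighbors_in_view(focal, school, tank=tank,
                              pellet_positions=pellets)
        expected = (separation_force(focal, p, school, W.w1, unit)
                    + cohesion_force(focal, p, school, W.w2)
                    + alignment_force(focal, p, school, W.w3)
                    + boundary_force(focal, tank, W.w4)
                    + feed_force(focal, p.nearest_pellet_position, W.w5, unit)
                    + W.w6 * unit)
        got = total_force(focal, school, tank, W, rand_unit=unit,
                          pellet_positions=pellets)
        np.testing.assert_allclose(got, expected, rtol=1e-12)


class TestKinematics:
    def test_cap_speed_standard_and_feeding(self):
        v = np.array([1.0, 0, 0])
        capped = cap_speed(v, "standard", 0.1408, W)
        np.testing.assert_allclose(capped, [1.5 * 0.1408, 0, 0], rtol=1e-12)
        capped = cap_speed(v, "feeding", 0.1408, W)
        np.testing.assert_allclose(capped, [7.0 * 0.1408, 0, 0], rtol=1e-12)
        slow = np.array([0.1, 0, 0])
        np.testing.assert_array_equal(cap_speed(slow, "standard", 0.1408, W),
                                      slow)

    def test_force_free_drift(self):
        tank = Tank(1.5, 1.5)
        fish = make_fish(0, (0, 0, 1.0), (0.1, 0, 0))
        integrate_step(fish, np.zeros(3), 0.025, tank, W)
        np.testing.assert_allclose(fish.position, [0.0025, 0, 1.0],
                                   rtol=1e-12)
        np.testing.assert_allclose(fish.velocity, [0.1, 0, 0], rtol=1e-12)

    def test_acceleration_then_cap(self):
        # F/m = 3.853 N / 0.03853 kg = 100 m/s^2; dt=0.025 -> 2.5 m/s pre-cap
        tank = Tank(1.5, 1.5)
        fish = make_fish(0, (0, 0, 1.0), (0, 0, 0), mass=38.53)
        integrate_step(fish, np.array([3.853, 0, 0]), 0.025, tank, W)
        vmax = 1.5 * fish.total_length
        np.testing.assert_allclose(fish.velocity, [vmax, 0, 0], rtol=1e-12)

    def test_non_finite_force_rejected(self):
        tank = Tank(1.5, 1.5)
        fish = make_fish(0)
        with pytest.raises(FloatingPointError):
            integrate_step(fish, np.array([np.nan, 0, 0]), 0.025, tank, W)

    def test_step_never_leaves_tank(self, rng):
        tank = Tank(1.5, 1.5)
        for _ in range(2000):
            r = tank.radius * np.sqrt(rng.random())
            th = rng.uniform(0, 2 * np.pi)
            fish = make_fish(
                0, (r * np.cos(th), r * np.sin(th),
                    rng.uniform(0, tank.depth)),
                rng.uniform(-1, 1, 3), mode="feeding")
            force = rng.uniform(-5, 5, 3)
            integrate_step(fish, force, 0.025, tank, W)
            x, y, z = fish.position
            assert math.hypot(x, y) <= tank.radius - WALL_EPS + 1e-12
            assert WALL_EPS - 1e-12 <= z <= tank.depth - WALL_EPS + 1e-12

    def test_deterministic_kernel_preserves_mirror_symmetry(self):
        # with w6 = 0, two fish placed mirror-symmetrically about the x-z
        # plane evolve mirror trajectories
        weights = BehaviorWeights(w6=0.0)
        tank = Tank(1.5, 1.5)
        a = make_fish(0, (0.3, 0.05, 0.75), (0.05, 0.02, 0.0))
        b = make_fish(1, (0.3, -0.05, 0.75), (0.05, -0.02, 0.0))
        school = [a, b]
        unit = np.array([1.0, 0.0, 0.0])  # unused: w6=0 contributes nothing
        for _ in range(200):
            forces = [total_force(f, school, tank, weights,
                                  rand_unit=unit) - weights.w6 * unit
                      for f in school]
            for f, force in zip(school, forces):
                integrate_step(f, force, 0.025, tank, weights)
            np.testing.assert_allclose(
                a.position * [1, -1, 1], b.position, atol=1e-10)
            np.testing.assert_allclose(
                a.velocity * [1, -1, 1], b.velocity, atol=1e-10)
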