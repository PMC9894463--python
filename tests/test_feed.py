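"""Pellet life cycle: geometry, spawning, sinking, consumption."""

import numpy as np
import pytest
from scipy import stats as sps

from schoolfeed import feeding_method_preset, spawn_pellets
from schoolfeed.config import Tank
from schoolfeed.feed import detect_and_consume, pellet_mass_from_geometry, sink
from schoolfeed.scenarios import make_fish, make_pellets


@pytest.mark.parametrize("d,rho,expected", [
    (0.005, 1.0, 0.065),   # the standard 5 mm pellet at water density
    (0.0, 1.0, 0.0),
    (0.010, 1.0, 0.524),
])
def test_pellet_mass_from_sphere_geometry(d, rho, expected):
    assert pellet_mass_from_geometry(d, rho) == expected


class TestSpawning:
    def test_day_one_ration_yields_1102_pellets(self, rng):
        # 1.86% of 100 x 38.53 g = 71.666 g -> floor(71.666 / 0.065)
        field = spawn_pellets(71.6658, feeding_method_preset("A"),
                              Tank(), rng)
        assert len(field) == 1102
        assert np.all(field.positions[:, 2] == Tank().depth)

    def test_single_pellet_ration(self, rng):
        field = spawn_pellets(0.065, feeding_method_preset("C"), Tank(), rng)
        assert len(field) == 1
        assert np.all(np.abs(field.positions[0, :2]) <= 0.25)

    def test_never_more_than_the_ration(self, rng):
        field = spawn_pellets(0.13 + 0.064, feeding_method_preset("B"),
                              Tank(), rng)
        assert len(field) == 2  # flooring, never rounding up

    def test_positions_uniform_over_square(self, rng):
        # one large spawn; x and y marginals uniform on [-0.25, 0.25]
        field = spawn_pellets(0.065 * 10000, feeding_method_preset("C"),
                              Tank(), rng)
        for axis in (0, 1):
            stat = sps.kstest(field.positions[:, axis],
                              sps.uniform(loc=-0.25, scale=0.5).cdf)
            assert stat.pvalue > 1e-3

    def test_zero_ration_rejected(self, rng):
        with pytest.raises(ValueError):
            spawn_pellets(0.0, feeding_method_preset("A"), Tank(), rng)


class TestSinking:
    def test_sink_rate_and_bottom_rest(self):
        field = make_pellets([[0, 0, 1.5]])
        sink(field, dt=0.025)
        assert field.positions[0, 2] == pytest.approx(1.5 - 0.025 * 0.025)
        # 1.5 m at 0.025 m/s -> bottom after 60 s
        field2 = make_pellets([[0, 0, 1.5]])
        for _ in range(2400):
            sink(field2, dt=0.025)
        assert field2.positions[0, 2] == 0.0
        sink(field2, dt=0.025)
        assert field2.positions[0, 2] == 0.0  # stays on the bottom


class TestConsumption:
    def test_feeding_fish_eats_coincident_pellet(self):
        fish = make_fish(0, (0, 0, 0.75), mode="feeding")
        field = make_pellets([[0, 0, 0.75]])
        events, _ = detect_and_consume([fish], field, time=0.025,
                                       rng=np.random.default_rng(0))
        assert len(events) == 1 and events[0].fish_id == 0
        assert not field.alive[0]
        assert fish.intake_today == pytest.approx(0.065)
        assert fish.pellets_today == 1

    def test_standard_mode_fish_swims_past_feed(self):
        fish = make_fish(0, (0, 0, 0.75), mode="standard")
        field = make_pellets([[0, 0, 0.75]])
        events, _ = detect_and_consume([fish], field, time=0.025,
                                       rng=np.random.default_rng(0))
        assert events == [] and field.alive[0]

    def test_satiated_fish_does_not_eat(self):
        fish = make_fish(0, (0, 0, 0.75), mode="feeding")
        fish.pellets_today = 24
        fish.intake_today = 24 * 0.065  # above Smax = 1.5412 g
        field = make_pellets([[0, 0, 0.75]])
        events, _ = detect_and_consume([fish], field, time=0.025,
                                       rng=np.random.default_rng(0))
        assert events == []

    def test_contested_pellet_tie_break_is_fair(self):
        wins = [0, 0]
        rng = np.random.default_rng(42)
        for _ in range(4000):
            a = make_fish(0, (0.001, 0, 0.75), mode="feeding")
            b = make_fish(1, (-0.001, 0, 0.75), mode="feeding")
            field = make_pellets([[0, 0, 0.75]])
            events, _ = detect_and_consume([a, b], field, 0.025, rng)
            wins[events[0].fish_id] += 1
        # binomial(4000, 0.5): 5 sigma is ~158
        assert abs(wins[0] - wins[1]) < 320

    def test_pellet_consumed_at_most_once_and_mass_conserved(self, rng):
        school = [make_fish(i, rng.uniform(-0.05, 0.05, 3) + [0, 0, 0.75],
                            mode="feeding") for i in range(5)]
        field = make_pellets(rng.uniform(-0.05, 0.05, (20, 3))
                             + [0, 0, 0.75])
        seen = set()
        for step in range(10):
            events, _ = detect_and_consume(school, field, 0.025 * step,
                                           rng=rng)
            for e in events:
                assert e.pellet_id not in seen
                seen.add(e.pellet_id)
        eaten = sum(f.pellets_today for f in school)
        assert eaten + field.n_alive == len(field)
        total_intake = sum(f.intake_today for f in school)
        assert total_intake + field.live_mass == pytest.approx(
            len(field) * field.pellet_mass, rel=1e-12)
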