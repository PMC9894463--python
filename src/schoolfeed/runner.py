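"""Orchestration of the multi-day rearing experiment.

A run couples the daily feeding loop with end-of-day growth: spawn the
day's ration over the feeding square, simulate the 1000 s feeding window,
convert each individual's intake to mass gain through the FCE, update total
length allometrically, and carry the final swimming state into the next day
(or re-randomize it, in the daily-randomization variant).

Randomness is organised as one ``numpy.random.SeedSequence`` per run:
child 0 seeds the initial school state, child ``d`` seeds day ``d``.
Within a day the stream is consumed in a fixed order — (variant only)
position/velocity re-randomization, pellet placement, the pellet tie-break
pool, then per-chunk wander directions — so runs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ExperimentConfig, feeding_method_preset
from .day import DayResult, School, run_feeding_day
from .feed import spawn_pellets
from .growth import daily_growth, length_from_mass

__all__ = [
    "ExperimentResult",
    "init_school",
    "daily_ration",
    "run_experiment",
    "run_methods_comparison",
    "derive_seed",
    "LEDGER_COLUMNS",
]

LEDGER_COLUMNS = ["day", "fish_id", "mass_g", "total_length_cm",
                  "intake_g", "pellets"]


@dataclass
class ExperimentResult:
    """Config snapshot, per-day per-fish ledger, and per-day summaries."""

    config: ExperimentConfig
    ledger: pd.DataFrame
    day_results: list[DayResult]
    final_school: School

    @property
    def final_day(self) -> int:
        return int(self.ledger["day"].max())

    def masses_on(self, day: int) -> np.ndarray:
        sub = self.ledger[self.ledger["day"] == day].sort_values("fish_id")
        return sub["mass_g"].to_numpy()


def _random_positions_velocities(config: ExperimentConfig, n: int,
                                 tl: np.ndarray, rng: np.random.Generator):
    """Uniform positions in the tank cylinder; random horizontal headings
    at the standard-mode cruising speed (so a school forms quickly)."""
    r = config.tank.radius * np.sqrt(rng.random(n))
    theta = 2.0 * np.pi * rng.random(n)
    z = rng.uniform(0.0, config.tank.depth, n)
    phi = 2.0 * np.pi * rng.random(n)
    speed = config.weights.cv_standard * tl
    return (r * np.cos(theta), r * np.sin(theta), z,
            speed * np.cos(phi), speed * np.sin(phi), np.zeros(n))


def init_school(config: ExperimentConfig, rng: np.random.Generator) -> School:
    """Identical initial masses; positions uniform in the tank cylinder."""
    n = config.n_fish
    mass = np.full(n, config.initial_mass, dtype=float)
    tl = length_from_mass(mass, config.allometry_a, config.allometry_b) / 100.0
    x, y, z, vx, vy, vz = _random_positions_velocities(config, n, tl, rng)
    return School(x, y, z, vx, vy, vz, tl, mass)


def daily_ration(school: School, config: ExperimentConfig) -> float:
    """Feed mass (g) distributed today: a fixed fraction of school biomass.

    The biomass base is the current school biomass by default; with
    ``ration_base="initial"`` the ration stays constant at
    ``ration_fraction * n_fish * initial_mass``.
    """
    if config.ration_base == "initial":
        biomass = config.n_fish * config.initial_mass
    else:
        biomass = float(np.sum(school.mass))
    return config.ration_fraction * biomass


def run_experiment(
    config: ExperimentConfig,
    *,
    engine: str = "fast",
    forced_full_consumption: bool = False,
    record_events: bool = False,
) -> ExperimentResult:
    """Run the full ``n_days`` experiment for one feeding method.

    ``forced_full_consumption`` bypasses the behavioral simulation and
    credits every fish with an equal 1/n share of the exact ration each
    day; with FCE = 1 and a current-biomass ration the school biomass then
    follows the closed form ``B(d) = B(0) * (1 + r)**d``, which serves as
    the analytic ceiling of mean growth.
    """
    ss = np.random.SeedSequence(config.rng_seed)
    children = ss.spawn(config.n_days + 1)
    school = init_school(config, np.random.default_rng(children[0]))
    rows_day = []
    rows_fish = []
    rows_mass = []
    rows_tl = []
    rows_intake = []
    rows_pellets = []
    day_results: list[DayResult] = []
    fish_ids = np.arange(config.n_fish)
    for day in range(1, config.n_days + 1):
        rng_day = np.random.default_rng(children[day])
        if config.randomize_daily and day > 1:
            x, y, z, vx, vy, vz = _random_positions_velocities(
                config, config.n_fish, school.total_length, rng_day)
            school.x[:], school.y[:], school.z[:] = x, y, z
            school.vx[:], school.vy[:], school.vz[:] = vx, vy, vz
        ration = daily_ration(school, config)
        if forced_full_consumption:
            intake = np.full(config.n_fish, ration / config.n_fish)
            school.intake[:] = intake
            school.neaten[:] = 0
            result = DayResult(
                day=day, intake_per_fish=intake.copy(),
                pellets_per_fish=school.neaten.copy(),
                pellets_spawned=0, pellets_eaten=0, completion_time=None,
                final_positions=school.positions,
                final_velocities=school.velocities)
        else:
            pellets = spawn_pellets(ration, config.feeding_method,
                                    config.tank, rng_day, config.pellet_mass)
            result = run_feeding_day(
                school, pellets, config, rng_day, day=day, engine=engine,
                early_stop=config.fast, record_events=record_events)
        day_results.append(result)
        school.mass[:] = daily_growth(school.mass, result.intake_per_fish,
                                      config.fce)
        tl_cm = length_from_mass(school.mass, config.allometry_a,
                                 config.allometry_b)
        school.total_length[:] = tl_cm / 100.0
        rows_day.append(np.full(config.n_fish, day))
        rows_fish.append(fish_ids)
        rows_mass.append(school.mass.copy())
        rows_tl.append(tl_cm)
        rows_intake.append(result.intake_per_fish)
        rows_pellets.append(result.pellets_per_fish)
    ledger = pd.DataFrame({
        "day": np.concatenate(rows_day),
        "fish_id": np.concatenate(rows_fish),
        "mass_g": np.concatenate(rows_mass),
        "total_length_cm": np.concatenate(rows_tl),
        "intake_g": np.concatenate(rows_intake),
        "pellets": np.concatenate(rows_pellets),
    })
    return ExperimentResult(config=config, ledger=ledger,
                            day_results=day_results, final_school=school)


def derive_seed(master_seed: int, *key: int) -> int:
    """Replicate seed derived from the master via SeedSequence spawn keys.

    Deterministic, documented, and collision-free across distinct keys;
    reduced below 2**31 so it remains a portable integer seed.
    """
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


def run_methods_comparison(
    base_config: ExperimentConfig,
    methods: Sequence[str] = ("A", "B", "C"),
    replicates: int = 1,
    master_seed: Optional[int] = None,
    *,
    engine: str = "fast",
) -> list[ExperimentResult]:
    """One run per (method, replicate), deterministically seeded.

    Run seeds are ``derive_seed(master, method_index, replicate)`` with the
    master defaulting to ``base_config.rng_seed``.  Results are ordered
    method-major.
    """
    master = base_config.rng_seed if master_seed is None else master_seed
    results = []
    for mi, name in enumerate(methods):
        method = feeding_method_preset(name)
        for rep in range(replicates):
            cfg = dataclasses.replace(
                base_config, feeding_method=method,
                rng_seed=derive_seed(master, mi, rep))
            results.append(run_experiment(cfg, engine=engine))
    return results
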