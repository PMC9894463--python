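"""One simulated feeding day: the 1000 s inner loop.

Each step proceeds in a fixed, documented order: resolve swimming modes
from the satiation state, perceive, compute forces, integrate all fish
synchronously, sink the pellets, then resolve fish-pellet contacts.  The
satiation cap ``Smax`` is computed from start-of-day mass (growth applies
only at day end).

Two engines implement the same model on identical random streams: the
compiled fast kernel (default) and a plain per-fish reference loop built
from the operations in :mod:`schoolfeed.behavior` and
:mod:`schoolfeed.feed`.  All randomness is pre-drawn in fixed-size chunks
from the day's numpy Generator — first the pellet tie-break pool (one
uniform per pellet), then per-chunk wander directions — so the engines
consume the stream identically; a given engine is bit-reproducible, and
the two agree to floating-point tolerance (the fast kernel may
reassociate neighbor sums).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import behavior as bhv
from . import feed as feed_mod
from ._kernel import GRID_CELL, build_pellet_grid, run_steps
from .config import ExperimentConfig
from .feed import IntakeEvent, PelletField

__all__ = ["School", "DayResult", "select_mode", "run_feeding_day", "CHUNK_STEPS"]

#: Steps per random-draw chunk (both engines use the same chunking).
CHUNK_STEPS = 2000


class School:
    """Structure-of-arrays state of the whole school.

    Positions/velocities in meters and m/s, total length in meters, mass in
    grams.  ``intake`` (g) and ``neaten`` (pellet counts) are the running
    within-day totals.
    """

    def __init__(self, x, y, z, vx, vy, vz, total_length, mass):
        as1d = lambda a: np.array(a, dtype=float).reshape(-1)
        self.x, self.y, self.z = as1d(x), as1d(y), as1d(z)
        self.vx, self.vy, self.vz = as1d(vx), as1d(vy), as1d(vz)
        self.total_length = as1d(total_length)
        self.mass = as1d(mass)
        self.intake = np.zeros(self.n)
        self.neaten = np.zeros(self.n, dtype=np.int64)

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y, self.z])

    @property
    def velocities(self) -> np.ndarray:
        return np.column_stack([self.vx, self.vy, self.vz])

    def to_states(self) -> list[bhv.FishState]:
        return [
            bhv.FishState(
                id=i,
                position=np.array([self.x[i], self.y[i], self.z[i]]),
                velocity=np.array([self.vx[i], self.vy[i], self.vz[i]]),
                mass=float(self.mass[i]),
                total_length=float(self.total_length[i]),
                intake_today=float(self.intake[i]),
                pellets_today=int(self.neaten[i]),
            )
            for i in range(self.n)
        ]

    def load_states(self, states: list[bhv.FishState]) -> None:
        for f in sorted(states, key=lambda s: s.id):
            i = f.id
            self.x[i], self.y[i], self.z[i] = f.position
            self.vx[i], self.vy[i], self.vz[i] = f.velocity
            self.intake[i] = f.intake_today
            self.neaten[i] = f.pellets_today

    @classmethod
    def from_states(cls, states: list[bhv.FishState]) -> "School":
        states = sorted(states, key=lambda s: s.id)
        sc = cls(
            [f.position[0] for f in states], [f.position[1] for f in states],
            [f.position[2] for f in states], [f.velocity[0] for f in states],
            [f.velocity[1] for f in states], [f.velocity[2] for f in states],
            [f.total_length for f in states], [f.mass for f in states])
        sc.intake[:] = [f.intake_today for f in states]
        sc.neaten[:] = [f.pellets_today for f in states]
        return sc


@dataclass
class DayResult:
    """Outcome of one feeding day."""

    day: int
    intake_per_fish: np.ndarray          # g, per fish
    pellets_per_fish: np.ndarray         # counts
    pellets_spawned: int
    pellets_eaten: int
    completion_time: Optional[float]     # s; None if feed remained at day end
    final_positions: np.ndarray          # (n, 3) m
    final_velocities: np.ndarray         # (n, 3) m/s
    events: Optional[list[IntakeEvent]] = None
    trajectory: Optional[np.ndarray] = None  # (snapshots, n, 3)
    trajectory_times: Optional[np.ndarray] = None


def select_mode(intake: float, mass: float, feed_present: bool,
                smax_fraction: float = 0.04) -> str:
    """Swimming-mode matrix: feeding iff feed is present and appetite remains.

    Appetite remains while the day's intake is below ``Smax`` (a fixed
    fraction of body mass); otherwise, or with no feed in the tank, the
    fish swims in standard mode.
    """
    if feed_present and intake < smax_fraction * mass:
        return "feeding"
    return "standard"


def _draw_raw_chunk(rng: np.random.Generator, k: int, n: int,
                    isotropic: bool) -> np.ndarray:
    """Pre-draw (k, n, 3) raw wander vectors for one chunk of steps.

    Vectors are normalized at the point of use (identically in both
    engines); exactly-zero draws are redrawn here.
    """
    if isotropic:
        raw = rng.standard_normal((k, n, 3))
    else:
        raw = rng.uniform(-1.0, 1.0, size=(k, n, 3))
    # an exactly-zero vector cannot be normalized; redraw it (P ~ 2**-159)
    if not raw.all():
        while True:
            bad = ~raw.any(axis=2)
            if not bad.any():
                break
            for a, b in np.argwhere(bad):
                raw[a, b] = (rng.standard_normal(3) if isotropic
                             else rng.uniform(-1.0, 1.0, 3))
    return raw


def _normalize3(v: np.ndarray) -> np.ndarray:
    a, b, c = float(v[0]), float(v[1]), float(v[2])
    return v / math.sqrt(a * a + b * b + c * c)


def run_feeding_day(
    school: School,
    pellets: PelletField,
    config: ExperimentConfig,
    rng: np.random.Generator,
    *,
    day: int = 1,
    engine: str = "fast",
    early_stop: bool = False,
    record_events: bool = False,
    trajectory_every: Optional[int] = None,
) -> DayResult:
    """Simulate one feeding day and return per-fish intake.

    ``school`` is advanced in place; its final kinematic state seeds the
    next day.  ``early_stop`` ends the inner loop shortly after the last
    pellet is eaten (intended for the daily-randomization variant where
    final positions are irrelevant).
    """
    if engine not in ("fast", "reference"):
        raise ValueError("engine must be 'fast' or 'reference'")
    n_steps = int(round(config.feeding_sim_duration / config.dt))
    school.intake[:] = 0.0
    school.neaten[:] = 0
    smax = school.mass * config.smax_fraction
    tie_u = rng.random(len(pellets))
    if engine == "fast":
        return _run_day_fast(school, pellets, config, rng, n_steps, smax,
                             tie_u, day, early_stop, record_events,
                             trajectory_every)
    return _run_day_reference(school, pellets, config, rng, n_steps, smax,
                              tie_u, day, early_stop, record_events)


def _run_day_fast(school, pellets, config, rng, n_steps, smax, tie_u, day,
                  early_stop, record_events, trajectory_every):
    n = school.n
    m = len(pellets)
    px = np.ascontiguousarray(pellets.positions[:, 0])
    py = np.ascontiguousarray(pellets.positions[:, 1])
    pz = np.ascontiguousarray(pellets.positions[:, 2])
    palive = pellets.alive
    cx, cy = config.feeding_method.square_center
    half = config.feeding_method.square_side / 2.0
    cell_start, cell_items, ncx, ncy = build_pellet_grid(
        px, py, cx - half, cy - half, config.feeding_method.square_side)
    feeding = np.zeros(n, dtype=np.uint8)
    ev_fish = np.zeros(m, dtype=np.int64)
    ev_pellet = np.zeros(m, dtype=np.int64)
    ev_step = np.zeros(m, dtype=np.int64)
    state_io = np.array([pellets.n_alive, 0, 0, -1], dtype=np.int64)
    cos_dead = math.cos(math.radians(config.dead_zone_half_angle))
    mass_div = 1000.0 if config.force_scale == "kg" else 1.0
    snapshots: list[np.ndarray] = []
    snap_times: list[float] = []
    snap_interval = None
    if trajectory_every is not None:
        snap_interval = max(
            CHUNK_STEPS,
            int(math.ceil(trajectory_every / CHUNK_STEPS)) * CHUNK_STEPS)
        snapshots.append(school.positions.copy())
        snap_times.append(0.0)
    done = 0
    while done < n_steps:
        k = min(CHUNK_STEPS, n_steps - done)
        units = _draw_raw_chunk(rng, k, n, config.isotropic_random)
        run_steps(
            school.x, school.y, school.z, school.vx, school.vy, school.vz,
            school.total_length, school.mass, school.intake, school.neaten,
            smax, feeding,
            px, py, pz, palive,
            cx - half, cy - half, GRID_CELL, ncx, ncy, cell_start, cell_items,
            units, tie_u,
            config.tank.radius, config.tank.depth, config.dt,
            config.weights.w1, config.weights.w2, config.weights.w3,
            config.weights.w4, config.weights.w5, config.weights.w6,
            config.weights.cv_standard, config.weights.cv_feeding,
            config.fov_radius_factor, cos_dead,
            config.pellet_diameter / 2.0, config.contact_radius_factor,
            config.sink_speed, pellets.pellet_mass,
            mass_div, bhv.WALL_EPS,
            done,
            ev_fish, ev_pellet, ev_step,
            state_io,
        )
        done += k
        if snap_interval is not None and done % snap_interval == 0:
            snapshots.append(school.positions.copy())
            snap_times.append(done * config.dt)
        if early_stop and state_io[0] == 0:
            break
    pellets.positions[:, 2] = pz
    completion = None
    if state_io[3] >= 0:
        completion = (int(state_io[3]) + 1) * config.dt
    events = None
    if record_events:
        events = [
            IntakeEvent(int(ev_fish[q]), int(ev_pellet[q]),
                        (int(ev_step[q]) + 1) * config.dt)
            for q in range(int(state_io[2]))
        ]
    return DayResult(
        day=day,
        intake_per_fish=school.intake.copy(),
        pellets_per_fish=school.neaten.copy(),
        pellets_spawned=m,
        pellets_eaten=m - int(state_io[0]),
        completion_time=completion,
        final_positions=school.positions,
        final_velocities=school.velocities,
        events=events,
        trajectory=np.array(snapshots) if snapshots else None,
        trajectory_times=np.array(snap_times) if snap_times else None,
    )


def _run_day_reference(school, pellets, config, rng, n_steps, smax, tie_u,
                       day, early_stop, record_events):
    """Per-fish reference engine; consumes the stream exactly like the fast one."""
    states = school.to_states()
    n = len(states)
    tie_counter = 0
    completion = None
    all_events: list[IntakeEvent] = []
    done = 0
    stop = False
    while done < n_steps and not stop:
        k = min(CHUNK_STEPS, n_steps - done)
        units = _draw_raw_chunk(rng, k, n, config.isotropic_random)
        for kk in range(k):
            feed_present = pellets.n_alive > 0
            for f in states:
                f.mode = select_mode(f.intake_today, f.mass, feed_present,
                                     config.smax_fraction)
            forces = [
                bhv.total_force(
                    f, states, config.tank, config.weights,
                    pellet_positions=pellets.positions,
                    pellet_alive=pellets.alive,
                    rand_unit=_normalize3(units[kk, f.id]),
                    fov_radius_factor=config.fov_radius_factor,
                    dead_zone_half_angle=config.dead_zone_half_angle,
                ) for f in states
            ]
            for f, force in zip(states, forces):
                bhv.integrate_step(f, force, config.dt, config.tank,
                                   config.weights,
                                   force_scale=config.force_scale)
            if pellets.n_alive > 0:
                feed_mod.sink(pellets, config.dt, config.sink_speed)
                events, tie_counter = feed_mod.detect_and_consume(
                    states, pellets, time=(done + kk + 1) * config.dt,
                    contact_radius_factor=config.contact_radius_factor,
                    pellet_diameter=config.pellet_diameter,
                    smax_fraction=config.smax_fraction,
                    tie_uniforms=tie_u, tie_counter=tie_counter)
                all_events.extend(events)
                if pellets.n_alive == 0 and completion is None:
                    completion = (done + kk + 1) * config.dt
        done += k
        if early_stop and pellets.n_alive == 0:
            stop = True
    school.load_states(states)
    return DayResult(
        day=day,
        intake_per_fish=school.intake.copy(),
        pellets_per_fish=school.neaten.copy(),
        pellets_spawned=len(pellets),
        pellets_eaten=len(pellets) - pellets.n_alive,
        completion_time=completion,
        final_positions=school.positions,
        final_velocities=school.velocities,
        events=all_events if record_events else None,
    )
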