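"""Micro-scenario builders: tiny schools and pellet batches for testing.

These construct fully explicit states (2-5 fish, a handful of pellets) so
that individual behavioral rules can be exercised and checked by hand or
against brute force.  They are first-class API: the same builders are handy
for exploring the behavioral kernel interactively.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .behavior import FishState
from .config import ExperimentConfig
from .day import School
from .feed import PelletField
from .growth import length_from_mass

__all__ = ["make_fish", "make_school", "make_pellets", "random_school",
           "random_pellets"]


def make_fish(fish_id: int = 0,
              position: Sequence[float] = (0.0, 0.0, 0.75),
              velocity: Sequence[float] = (0.0, 0.0, 0.0),
              mass: float = 38.53,
              mode: str = "standard",
              total_length: Optional[float] = None) -> FishState:
    """One fish; total length defaults to the allometric value (meters)."""
    if total_length is None:
        total_length = float(length_from_mass(mass)) / 100.0
    return FishState(id=fish_id, position=np.asarray(position, float),
                     velocity=np.asarray(velocity, float), mass=mass,
                     total_length=total_length, mode=mode)


def make_school(positions: Sequence[Sequence[float]],
                velocities: Optional[Sequence[Sequence[float]]] = None,
                mass: float = 38.53,
                mode: str = "standard") -> list[FishState]:
    """A small school with ids 0..n-1 at the given positions."""
    if velocities is None:
        velocities = [(0.0, 0.0, 0.0)] * len(positions)
    return [make_fish(i, p, v, mass=mass, mode=mode)
            for i, (p, v) in enumerate(zip(positions, velocities))]


def make_pellets(positions: Sequence[Sequence[float]],
                 pellet_mass: float = 0.065) -> PelletField:
    """Pellets at explicit positions."""
    return PelletField(np.asarray(positions, float), pellet_mass)


def random_school(n: int, rng: np.random.Generator,
                  config: Optional[ExperimentConfig] = None,
                  mass_range: tuple[float, float] = (30.0, 60.0)) -> School:
    """Random valid school state inside the tank, varied masses and speeds."""
    config = config or ExperimentConfig()
    r = config.tank.radius * 0.9 * np.sqrt(rng.random(n))
    theta = 2 * np.pi * rng.random(n)
    z = rng.uniform(0.05, config.tank.depth - 0.05, n)
    mass = rng.uniform(*mass_range, n)
    tl = length_from_mass(mass, config.allometry_a, config.allometry_b) / 100.0
    speed = rng.uniform(0.0, config.weights.cv_standard * tl)
    phi = 2 * np.pi * rng.random(n)
    cosang = rng.uniform(-1, 1, n)
    sinang = np.sqrt(1 - cosang ** 2)
    return School(r * np.cos(theta), r * np.sin(theta), z,
                  speed * sinang * np.cos(phi), speed * sinang * np.sin(phi),
                  speed * cosang, tl, mass)


def random_pellets(n: int, rng: np.random.Generator,
                   config: Optional[ExperimentConfig] = None) -> PelletField:
    """Pellets scattered over the configured feeding square, random depths."""
    config = config or ExperimentConfig()
    cx, cy = config.feeding_method.square_center
    half = config.feeding_method.square_side / 2.0
    xy = rng.uniform(-half, half, (n, 2))
    z = rng.uniform(0.0, config.tank.depth, n)
    pos = np.column_stack([cx + xy[:, 0], cy + xy[:, 1], z])
    return PelletField(pos, config.pellet_mass)
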