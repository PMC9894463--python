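"""Feed-pellet life cycle: spawning, sinking and contact-based consumption.

Pellets are identical spheres (default 5.0 mm diameter at the density of
water, hence 0.065 g each).  A day's ration is converted to a pellet count
by flooring, the pellets are scattered uniformly over the feeding square at
the water surface at t = 0, and they sink at a fixed speed until they rest
on the bottom, where they remain edible until the feeding window ends.

Consumption is contact-based: a pellet within the "mouth sphere" of a
feeding-mode fish (radius ``pellet_radius + contact_radius_factor * TL``)
is eaten and removed in the same step.  When several fish contact the same
pellet the eater is chosen uniformly at random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .behavior import FishState
from .config import FeedingMethod, Tank

__all__ = [
    "PelletField",
    "IntakeEvent",
    "pellet_mass_from_geometry",
    "spawn_pellets",
    "sink",
    "detect_and_consume",
]


@dataclass(frozen=True)
class IntakeEvent:
    fish_id: int
    pellet_id: int
    time: float  # s within the feeding window


class PelletField:
    """Live feed pellets, stored as parallel arrays for speed.

    ``positions`` is an (m, 3) float array; ``alive`` a boolean mask.
    Pellet ids are the row indices.  All pellets share one ``pellet_mass``.
    """

    def __init__(self, positions: np.ndarray, pellet_mass: float):
        self.positions = np.array(positions, dtype=float).reshape(-1, 3)
        self.alive = np.ones(len(self.positions), dtype=bool)
        self.pellet_mass = float(pellet_mass)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    @property
    def live_mass(self) -> float:
        """Total mass (g) of uneaten pellets."""
        return self.n_alive * self.pellet_mass


def pellet_mass_from_geometry(diameter: float, density: float = 1.0) -> float:
    """Mass in grams of a spherical pellet of ``diameter`` meters.

    ``density`` is in g/cm^3 (water = 1.0).  The result is rounded to three
    decimals, matching the precision at which the default constant is
    carried (5.0 mm at water density -> 0.065 g).
    """
    if diameter < 0:
        raise ValueError("diameter must be >= 0")
    d_cm = diameter * 100.0
    return round(math.pi / 6.0 * d_cm ** 3 * density, 3)


def spawn_pellets(
    ration: float,
    method: FeedingMethod,
    tank: Tank,
    rng: np.random.Generator,
    pellet_mass: float = 0.065,
) -> PelletField:
    """Scatter a day's ration over the feeding square at the surface.

    The pellet count is ``floor(ration / pellet_mass)`` — never more feed
    than prescribed.  Horizontal positions are i.i.d. uniform over the
    square; all pellets start at the water surface (z = depth).
    """
    if not ration > 0:
        raise ValueError("ration must be > 0")
    method.validate_in_tank(tank)
    count = int(math.floor(ration / pellet_mass + 1e-9))
    cx, cy = method.square_center
    half = method.square_side / 2.0
    xy = rng.uniform(-half, half, size=(count, 2))
    positions = np.column_stack([
        cx + xy[:, 0], cy + xy[:, 1], np.full(count, tank.depth)])
    return PelletField(positions, pellet_mass)


def sink(pellets: PelletField, dt: float, sink_speed: float = 0.025) -> PelletField:
    """Advance sinking by one step; pellets rest on the bottom at z = 0."""
    z = pellets.positions[:, 2]
    np.maximum(z - sink_speed * dt, 0.0, out=z)
    return pellets


def detect_and_consume(
    school: Sequence[FishState],
    pellets: PelletField,
    time: float,
    rng: Optional[np.random.Generator] = None,
    *,
    contact_radius_factor: float = 0.1,
    pellet_diameter: float = 0.005,
    smax_fraction: float = 0.04,
    tie_uniforms: Optional[np.ndarray] = None,
    tie_counter: int = 0,
) -> tuple[list[IntakeEvent], int]:
    """Resolve fish-pellet contacts for one step, mutating both sides.

    A pellet is eaten by fish *i* when the pellet center lies within
    ``pellet_radius + contact_radius_factor * TL_i`` of the fish position,
    fish *i* entered the step in feeding mode, and its intake is still
    below the satiation cap (the live cap check keeps the overshoot below
    one pellet mass even when a fish meets several pellets in one step).
    Ties are broken uniformly at random, either from ``rng`` or from a
    pre-drawn ``tie_uniforms`` pool (used by the fast engine so both
    engines consume identical streams).

    Returns the intake events and the updated tie-pool counter.
    """
    events: list[IntakeEvent] = []
    pellet_radius = pellet_diameter / 2.0
    order = sorted(school, key=lambda f: f.id)
    for pid in range(len(pellets)):
        if not pellets.alive[pid]:
            continue
        ppos = pellets.positions[pid]
        contacts: list[FishState] = []
        for fish in order:
            if fish.mode != "feeding":
                continue
            if fish.intake_today >= smax_fraction * fish.mass:
                continue
            rc = pellet_radius + contact_radius_factor * fish.total_length
            dx = float(ppos[0]) - float(fish.position[0])
            dy = float(ppos[1]) - float(fish.position[1])
            dz = float(ppos[2]) - float(fish.position[2])
            if dx * dx + dy * dy + dz * dz <= rc * rc:
                contacts.append(fish)
        if not contacts:
            continue
        if tie_uniforms is not None:
            u = float(tie_uniforms[tie_counter])
            tie_counter += 1
        elif rng is not None:
            u = float(rng.random())
        else:
            raise ValueError("either rng or tie_uniforms is required")
        eater = contacts[min(int(u * len(contacts)), len(contacts) - 1)]
        pellets.alive[pid] = False
        eater.pellets_today += 1
        # intake is count x pellet mass by definition; kept exact this way
        eater.intake_today = eater.pellets_today * pellets.pellet_mass
        events.append(IntakeEvent(eater.id, pid, time))
    return events, tie_counter
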