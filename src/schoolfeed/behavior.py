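"""Per-time-step behavioral kernel, reference implementation.

Each fish steers by six local rules (separation, cohesion, alignment,
boundary avoidance, feed attraction, random movement).  The resulting force
sum enters a Newtonian update with a per-mode speed cap proportional to
total length: standard-mode cruising at 1.5 body lengths per second,
feeding-mode bursts at 7 body lengths per second.

Perception is a sphere of radius ``fov_radius_factor * TL`` (default two
body lengths) minus a rear blind cone of half-angle 30 degrees about the
backward direction; feed is detected regardless of the field of view.

Every rule force has magnitude exactly equal to its weight, or zero when
the interaction is absent; the dynamics are therefore governed by the
directions of the rules and by the speed cap rather than by force
magnitudes.

This module is the plain, per-fish implementation used for micro-scenarios
and as the brute-force oracle; production runs go through the vectorized
fast kernel (see :mod:`schoolfeed._kernel`), which is tested for
equivalence against these functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import BehaviorWeights, Tank

__all__ = [
    "FishState",
    "Perception",
    "neighbors_in_view",
    "separation_force",
    "cohesion_force",
    "alignment_force",
    "boundary_force",
    "feed_force",
    "random_force",
    "random_unit_vector",
    "total_force",
    "cap_speed",
    "integrate_step",
    "WALL_EPS",
]

#: Clamping margin (m) kept between a fish and any tank boundary.
WALL_EPS = 1e-3


@dataclass
class FishState:
    """Kinematic and physiological state of one individual."""

    id: int
    position: np.ndarray
    velocity: np.ndarray
    mass: float                     # g
    total_length: float             # m
    mode: str = "standard"          # "standard" | "feeding"
    intake_today: float = 0.0       # g
    pellets_today: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).copy()
        self.velocity = np.asarray(self.velocity, dtype=float).copy()


@dataclass
class Perception:
    """What one fish currently perceives."""

    neighbor_ids: list[int] = field(default_factory=list)
    nearest_neighbor_id: Optional[int] = None
    nearest_boundary_point: Optional[np.ndarray] = None
    nearest_pellet_position: Optional[np.ndarray] = None


def _unit(v: np.ndarray) -> Optional[np.ndarray]:
    # explicit scalar arithmetic so the fast kernel can match it exactly
    a, b, c = float(v[0]), float(v[1]), float(v[2])
    n = math.sqrt(a * a + b * b + c * c)
    if n == 0.0:
        return None
    return v / n


def neighbors_in_view(
    focal: FishState,
    school: Sequence[FishState],
    fov_radius_factor: float = 2.0,
    dead_zone_half_angle: float = 30.0,
    tank: Optional[Tank] = None,
    pellet_positions: Optional[np.ndarray] = None,
    pellet_alive: Optional[np.ndarray] = None,
) -> Perception:
    """Perceive neighbors (and optionally the nearest boundary and pellet).

    A neighbor is any other fish within ``fov_radius_factor * TL`` of the
    focal position that does not lie inside the rear blind cone (half-angle
    ``dead_zone_half_angle`` degrees about ``-velocity``).  When the focal
    fish is at rest the blind cone is undefined and treated as absent.
    Feed is perceived regardless of the field of view.
    """
    p = Perception()
    radius = fov_radius_factor * focal.total_length
    r2 = radius * radius
    vx, vy, vz = (float(c) for c in focal.velocity)
    spd2 = vx * vx + vy * vy + vz * vz
    cos_dead = math.cos(math.radians(dead_zone_half_angle))
    cd2spd2 = (cos_dead * cos_dead) * spd2
    best_d2 = math.inf
    xi, yi, zi = (float(c) for c in focal.position)
    for other in school:
        if other.id == focal.id:
            continue
        dx = float(other.position[0]) - xi
        dy = float(other.position[1]) - yi
        dz = float(other.position[2]) - zi
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > r2:
            continue
        if spd2 > 0.0 and d2 > 0.0:
            # inside dead cone iff angle(d, -v) < half-angle (squared form)
            dot_back = dx * (-vx) + dy * (-vy) + dz * (-vz)
            if dot_back > 0.0 and dot_back * dot_back > cd2spd2 * d2:
                continue
        p.neighbor_ids.append(other.id)
        if d2 < best_d2:
            best_d2 = d2
            p.nearest_neighbor_id = other.id
    if tank is not None:
        p.nearest_boundary_point = nearest_boundary_in_view(
            focal.position, tank, radius)
    if pellet_positions is not None and len(pellet_positions):
        alive = (np.ones(len(pellet_positions), dtype=bool)
                 if pellet_alive is None else np.asarray(pellet_alive, bool))
        best = math.inf
        best_p = -1
        for pid in range(len(pellet_positions)):
            if not alive[pid]:
                continue
            dx = float(pellet_positions[pid, 0]) - xi
            dy = float(pellet_positions[pid, 1]) - yi
            dz = float(pellet_positions[pid, 2]) - zi
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < best:
                best = d2
                best_p = pid
        if best_p >= 0:
            p.nearest_pellet_position = np.array(
                pellet_positions[best_p], dtype=float)
    return p


def nearest_boundary_in_view(
    position: np.ndarray, tank: Tank, view_radius: float
) -> Optional[np.ndarray]:
    """Nearest point among {wall, bottom, surface} within the view sphere.

    Candidates are the radial projection onto the cylindrical wall, and the
    vertical projections onto the bottom and surface planes.  Ties resolve
    in the fixed order wall, bottom, surface.
    """
    x, y, z = (float(c) for c in position)
    rxy = math.sqrt(x * x + y * y)
    candidates: list[tuple[float, np.ndarray]] = []
    if rxy > 0.0:
        scale = tank.radius / rxy
        candidates.append((tank.radius - rxy, np.array([x * scale, y * scale, z])))
    else:
        candidates.append((tank.radius, np.array([tank.radius, 0.0, z])))
    candidates.append((z, np.array([x, y, 0.0])))
    candidates.append((tank.depth - z, np.array([x, y, tank.depth])))
    best: Optional[np.ndarray] = None
    best_d = math.inf
    for d, point in candidates:
        if d <= view_radius and d < best_d:
            best_d = d
            best = point
    return best


def separation_force(
    focal: FishState,
    perception: Perception,
    school: Sequence[FishState],
    w1: float,
    fallback_dir: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Repulsion from the nearest in-view individual, magnitude ``w1``.

    Coincident positions (zero separation) fall back to ``fallback_dir``,
    a seeded random unit vector supplied by the caller.
    """
    if perception.nearest_neighbor_id is None:
        return np.zeros(3)
    other = next(f for f in school if f.id == perception.nearest_neighbor_id)
    u = _unit(focal.position - other.position)
    if u is None:
        u = fallback_dir if fallback_dir is not None else np.array([1.0, 0.0, 0.0])
    return w1 * u


def cohesion_force(
    focal: FishState,
    perception: Perception,
    school: Sequence[FishState],
    w2: float,
) -> np.ndarray:
    """Attraction toward the centroid of in-view neighbors, magnitude ``w2``."""
    if not perception.neighbor_ids:
        return np.zeros(3)
    ids = set(perception.neighbor_ids)
    centroid = np.zeros(3)
    m = 0
    for f in school:  # in-order accumulation (matches the fast kernel exactly)
        if f.id in ids:
            centroid += f.position
            m += 1
    centroid /= m
    u = _unit(centroid - focal.position)
    if u is None:  # focal exactly at the centroid
        return np.zeros(3)
    return w2 * u


def alignment_force(
    focal: FishState,
    perception: Perception,
    school: Sequence[FishState],
    w3: float,
) -> np.ndarray:
    """Steer toward the mean heading of in-view neighbors, magnitude ``w3``."""
    if not perception.neighbor_ids:
        return np.zeros(3)
    ids = set(perception.neighbor_ids)
    vbar = np.zeros(3)
    m = 0
    for f in school:
        if f.id in ids:
            vbar += f.velocity
            m += 1
    vbar /= m
    u = _unit(vbar - focal.velocity)
    if u is None:  # already aligned
        return np.zeros(3)
    return w3 * u


def boundary_force(
    focal: FishState,
    tank: Tank,
    w4: float,
    fov_radius_factor: float = 2.0,
) -> np.ndarray:
    """Repulsion from the nearest in-view tank boundary, magnitude ``w4``."""
    point = nearest_boundary_in_view(
        focal.position, tank, fov_radius_factor * focal.total_length)
    if point is None:
        return np.zeros(3)
    u = _unit(focal.position - point)
    if u is None:
        return np.zeros(3)
    return w4 * u


def feed_force(
    focal: FishState,
    nearest_pellet: Optional[np.ndarray],
    w5_mode: float,
    fallback_dir: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Attraction toward the nearest live pellet.

    ``w5_mode`` is the mode-resolved weight: 3.0 in feeding mode, 0.0 in
    standard mode.  Feed detection ignores the field of view.
    """
    if nearest_pellet is None or w5_mode == 0.0:
        return np.zeros(3)
    u = _unit(np.asarray(nearest_pellet, float) - focal.position)
    if u is None:
        u = fallback_dir if fallback_dir is not None else np.array([1.0, 0.0, 0.0])
    return w5_mode * u


def random_unit_vector(rng: np.random.Generator, isotropic: bool = False) -> np.ndarray:
    """Random direction for the wander rule.

    Default scheme: draw (x1, x2, x3) uniform on [-1, 1]^3 and normalize.
    This cube-then-normalize direction distribution is *not* uniform on the
    sphere (corner directions are over-represented); it is kept as the
    model's literal wander rule.  ``isotropic=True`` switches to a uniform
    spherical direction via normalized Gaussians.
    """
    while True:
        if isotropic:
            v = rng.standard_normal(3)
        else:
            v = rng.uniform(-1.0, 1.0, 3)
        n = float(np.linalg.norm(v))
        if n > 0.0:
            return v / n


def random_force(
    rng: np.random.Generator, w6: float, isotropic: bool = False
) -> np.ndarray:
    """Random wander force of magnitude exactly ``w6``."""
    return w6 * random_unit_vector(rng, isotropic=isotropic)


def total_force(
    focal: FishState,
    school: Sequence[FishState],
    tank: Tank,
    weights: BehaviorWeights,
    rng: Optional[np.random.Generator] = None,
    *,
    perception: Optional[Perception] = None,
    pellet_positions: Optional[np.ndarray] = None,
    pellet_alive: Optional[np.ndarray] = None,
    rand_unit: Optional[np.ndarray] = None,
    fov_radius_factor: float = 2.0,
    dead_zone_half_angle: float = 30.0,
    isotropic_random: bool = False,
) -> np.ndarray:
    """Sum of the six rule forces for the focal fish.

    The random direction can be supplied directly (``rand_unit``) for
    reproducible, stream-controlled stepping, or drawn from ``rng``.
    """
    if perception is None:
        perception = neighbors_in_view(
            focal, school, fov_radius_factor, dead_zone_half_angle,
            tank=tank, pellet_positions=pellet_positions,
            pellet_alive=pellet_alive)
    if rand_unit is None:
        if rng is None:
            raise ValueError("either rand_unit or rng is required")
        rand_unit = random_unit_vector(rng, isotropic=isotropic_random)
    w5_mode = weights.w5 if focal.mode == "feeding" else 0.0
    f = separation_force(focal, perception, school, weights.w1,
                         fallback_dir=rand_unit)
    f = f + cohesion_force(focal, perception, school, weights.w2)
    f = f + alignment_force(focal, perception, school, weights.w3)
    f = f + boundary_force(focal, tank, weights.w4, fov_radius_factor)
    f = f + feed_force(focal, perception.nearest_pellet_position, w5_mode,
                       fallback_dir=rand_unit)
    f = f + weights.w6 * rand_unit
    return f


def cap_speed(
    velocity: np.ndarray,
    mode: str,
    total_length: float,
    weights: BehaviorWeights,
) -> np.ndarray:
    """Rescale velocity to the per-mode cap ``Cv * TL`` when it is exceeded."""
    cv = weights.cv_feeding if mode == "feeding" else weights.cv_standard
    vmax = cv * total_length
    a, b, c = float(velocity[0]), float(velocity[1]), float(velocity[2])
    speed = math.sqrt(a * a + b * b + c * c)
    if speed > vmax:
        return velocity * (vmax / speed)
    return np.asarray(velocity, dtype=float)


def integrate_step(
    focal: FishState,
    force: np.ndarray,
    dt: float,
    tank: Tank,
    weights: BehaviorWeights,
    force_scale: str = "kg",
) -> FishState:
    """Semi-implicit Euler update of one fish, in place.

    ``a = F / m`` with mass in kilograms by default (``force_scale="kg"``);
    velocity is updated first, capped, and the new velocity advances the
    position.  The position is then clamped to the tank interior with the
    outward velocity component zeroed.
    """
    force = np.asarray(force, dtype=float)
    if not np.all(np.isfinite(force)):
        raise FloatingPointError(f"non-finite force for fish {focal.id}: {force}")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    m = focal.mass / 1000.0 if force_scale == "kg" else focal.mass
    v = focal.velocity + (force / m) * dt
    v = cap_speed(v, focal.mode, focal.total_length, weights)
    x = focal.position + v * dt
    x, v = clamp_to_tank(x, v, tank)
    focal.velocity = v
    focal.position = x
    return focal


def clamp_to_tank(
    position: np.ndarray, velocity: np.ndarray, tank: Tank
) -> tuple[np.ndarray, np.ndarray]:
    """Clamp a position to the tank interior, zeroing outward velocity.

    The radial coordinate is clamped to ``radius - WALL_EPS`` and z to
    ``[WALL_EPS, depth - WALL_EPS]``.
    """
    x, y, z = (float(c) for c in position)
    vx, vy, vz = (float(c) for c in velocity)
    rmax = tank.radius - WALL_EPS
    rxy = math.sqrt(x * x + y * y)
    if rxy > rmax:
        s = rmax / rxy
        x *= s
        y *= s
        # zero the outward radial velocity component
        ux, uy = x / rmax, y / rmax
        vr = vx * ux + vy * uy
        if vr > 0.0:
            vx -= vr * ux
            vy -= vr * uy
    if z < WALL_EPS:
        z = WALL_EPS
        if vz < 0.0:
            vz = 0.0
    elif z > tank.depth - WALL_EPS:
        z = tank.depth - WALL_EPS
        if vz > 0.0:
            vz = 0.0
    return np.array([x, y, z]), np.array([vx, vy, vz])
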