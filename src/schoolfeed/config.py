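"""Central, validated parameterization of the simulator.

Unit conventions are fixed here once: positions and velocities are in meters
and meters/second, body mass in grams, and total length is carried in meters
throughout the behavioral code.  The allometric coefficients ``a`` and ``b``
were fitted for length in centimeters and mass in grams, so length is
converted to centimeters only inside the allometric relation
(``W = 0.0209 * 14.08**2.843 ~ 38.5 g`` confirms the convention).

Coordinate frame: the z axis is vertical with ``z = 0`` at the tank bottom
and the water surface at ``z = depth``; the tank axis passes through the
horizontal origin.  Sinking feed is then a pure decrement of z.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any, TextIO, Union

import yaml

__all__ = [
    "BehaviorWeights",
    "Tank",
    "FeedingMethod",
    "ExperimentConfig",
    "ConfigError",
    "load_config",
    "dump_config",
    "config_from_dict",
    "config_to_dict",
    "feeding_method_preset",
]


class ConfigError(ValueError):
    """Raised when a configuration value violates an invariant."""


@dataclass(frozen=True)
class BehaviorWeights:
    """Weights of the six behavioral rule forces and the speed-cap coefficients.

    ``w1``..``w6`` weight separation, cohesion, alignment, boundary
    avoidance, feed attraction and random movement.  ``w5`` is the
    feeding-mode value; in standard mode the feed attraction is zero.
    ``cv_standard``/``cv_feeding`` multiply total length (per second) to give
    the per-mode maximum swimming speed.
    """

    w1: float = 0.6
    w2: float = 0.4
    w3: float = 0.4
    w4: float = 1.0
    w5: float = 3.0
    w6: float = 0.2
    cv_standard: float = 1.5
    cv_feeding: float = 7.0

    def __post_init__(self) -> None:
        for name in ("w1", "w2", "w3", "w4", "w5", "w6"):
            if getattr(self, name) < 0:
                raise ConfigError(f"weight {name} must be >= 0")
        if not self.cv_standard > 0:
            raise ConfigError("cv_standard must be > 0")
        if self.cv_feeding < self.cv_standard:
            raise ConfigError("cv_feeding must be >= cv_standard")


@dataclass(frozen=True)
class Tank:
    """Cylindrical tank: ``radius`` and water ``depth``, both in meters."""

    radius: float = 1.5
    depth: float = 1.5

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ConfigError("tank radius must be > 0")
        if not self.depth > 0:
            raise ConfigError("tank depth must be > 0")


@dataclass(frozen=True)
class FeedingMethod:
    """Square feed-distribution footprint at the water surface.

    ``square_side`` is the side length in meters; ``square_center`` is the
    horizontal (x, y) center, by default the tank axis.
    """

    name: str = "A"
    square_side: float = 1.5
    square_center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.square_side > 0:
            raise ConfigError("square_side must be > 0")

    def validate_in_tank(self, tank: Tank) -> None:
        """Check the square footprint is inscribed inside the tank circle."""
        cx, cy = self.square_center
        half = self.square_side / 2.0
        # farthest corner of the square from the tank axis
        corner = max(
            math.hypot(cx + sx * half, cy + sy * half)
            for sx in (-1, 1)
            for sy in (-1, 1)
        )
        if corner > tank.radius + 1e-12:
            raise ConfigError(
                f"square exceeds tank: corner radius {corner:.3f} m > "
                f"tank radius {tank.radius:.3f} m (square_side)"
            )


#: Side lengths (m) of the three standard feed-distribution squares.
METHOD_SIDES = {"A": 1.5, "B": 1.0, "C": 0.5}


def feeding_method_preset(name: str) -> FeedingMethod:
    """Return one of the standard feeding methods A, B or C.

    The feed square is centered on the tank axis with side length 1.5, 1.0
    or 0.5 m respectively.
    """
    try:
        side = METHOD_SIDES[name]
    except KeyError:
        raise ConfigError(
            f"unknown feeding method {name!r}; expected one of A, B, C"
        ) from None
    return FeedingMethod(name=name, square_side=side)


@dataclass(frozen=True)
class ExperimentConfig:
    """Full parameterization of one simulated rearing experiment.

    Defaults reproduce the standard study conditions: 100 rainbow trout of
    38.53 g in a 3.0 m diameter x 1.5 m deep tank, fed once per day with
    1.86% of the school biomass as 0.065 g pellets over a 1000 s feeding
    window, for 90 days.
    """

    n_fish: int = 100
    initial_mass: float = 38.53          # g
    ration_fraction: float = 0.0186      # fraction of school biomass per day
    ration_base: str = "current"         # "current" | "initial" biomass
    fce: float = 1.0                     # feed conversion efficiency
    smax_fraction: float = 0.04          # satiation cap, fraction of body mass
    pellet_mass: float = 0.065           # g
    pellet_diameter: float = 0.005       # m
    sink_speed: float = 0.025            # m/s
    dt: float = 0.025                    # s
    feeding_sim_duration: float = 1000.0  # s per day
    n_days: int = 90
    randomize_daily: bool = False
    fast: bool = False                   # early-exit inner loop (needs randomize_daily)
    rng_seed: int = 0
    feeding_method: FeedingMethod = field(
        default_factory=lambda: feeding_method_preset("A"))
    weights: BehaviorWeights = field(default_factory=BehaviorWeights)
    tank: Tank = field(default_factory=Tank)
    allometry_a: float = 0.0209          # g per cm**b
    allometry_b: float = 2.843
    fov_radius_factor: float = 2.0       # field-of-view radius in body lengths
    dead_zone_half_angle: float = 30.0   # degrees, rear blind cone
    contact_radius_factor: float = 0.1   # mouth sphere radius in body lengths
                                         # (day-1 feeding completes well within
                                         # the ~30 s observed for the 1.5 m square)
    force_scale: str = "kg"              # "kg": a = F / (mass in kg); "g": grams
    isotropic_random: bool = False       # Gaussian-direction F6 instead of cube-normalized

    def __post_init__(self) -> None:
        checks = [
            (self.n_fish >= 1, "n_fish must be >= 1"),
            (self.initial_mass > 0, "initial_mass must be > 0"),
            (0 < self.ration_fraction < 1, "ration_fraction must be in (0, 1)"),
            (self.ration_base in ("current", "initial"),
             "ration_base must be 'current' or 'initial'"),
            (self.fce > 0, "fce must be > 0"),
            (0 < self.smax_fraction < 1, "smax_fraction must be in (0, 1)"),
            (self.pellet_mass > 0, "pellet_mass must be > 0"),
            (self.pellet_diameter > 0, "pellet_diameter must be > 0"),
            (self.sink_speed >= 0, "sink_speed must be >= 0"),
            (self.dt > 0, "dt must be > 0"),
            (self.feeding_sim_duration > 0, "feeding_sim_duration must be > 0"),
            (self.n_days >= 1, "n_days must be >= 1"),
            (self.allometry_a > 0, "allometry_a must be > 0"),
            (self.allometry_b > 0, "allometry_b must be > 0"),
            (self.fov_radius_factor > 0, "fov_radius_factor must be > 0"),
            (0 < self.dead_zone_half_angle < 180,
             "dead_zone_half_angle must be in (0, 180) degrees"),
            (self.contact_radius_factor >= 0,
             "contact_radius_factor must be >= 0"),
            (self.force_scale in ("kg", "g"), "force_scale must be 'kg' or 'g'"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)
        if self.fast and not self.randomize_daily:
            raise ConfigError("fast mode requires randomize_daily")
        self.feeding_method.validate_in_tank(self.tank)

    # -- convenience -------------------------------------------------------
    def with_overrides(self, **kw: Any) -> "ExperimentConfig":
        """Return a copy with the given top-level fields replaced."""
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# serialization

def config_to_dict(config: ExperimentConfig) -> dict[str, Any]:
    """Plain-dict (YAML-safe) representation of a config."""
    d = dataclasses.asdict(config)
    d["feeding_method"]["square_center"] = list(config.feeding_method.square_center)
    return d


def config_from_dict(data: dict[str, Any]) -> ExperimentConfig:
    """Build a validated config from a (possibly partial) plain dict.

    Missing fields take the default study values.  Unknown keys raise
    :class:`ConfigError` so typos do not silently fall back to defaults.
    """
    data = dict(data or {})
    kwargs: dict[str, Any] = {}
    nested = {
        "feeding_method": FeedingMethod,
        "weights": BehaviorWeights,
        "tank": Tank,
    }
    field_names = {f.name for f in dataclasses.fields(ExperimentConfig)}
    for key, value in data.items():
        if key not in field_names:
            raise ConfigError(f"unknown config key {key!r}")
        if key in nested and isinstance(value, dict):
            sub = dict(value)
            if key == "feeding_method" and "square_center" in sub:
                sub["square_center"] = tuple(sub["square_center"])
            try:
                kwargs[key] = nested[key](**sub)
            except TypeError as exc:
                raise ConfigError(f"bad {key} section: {exc}") from exc
        else:
            kwargs[key] = value
    return ExperimentConfig(**kwargs)


def load_config(source: Union[str, TextIO, None] = None, **overrides: Any) -> ExperimentConfig:
    """Load a config from YAML text, a file object, or nothing (defaults).

    ``overrides`` are applied on top of the parsed values and take
    precedence, mirroring CLI-flag semantics.
    """
    if source is None:
        data: dict[str, Any] = {}
    elif isinstance(source, str):
        data = yaml.safe_load(source) or {}
    else:
        data = yaml.safe_load(source.read()) or {}
    if not isinstance(data, dict):
        raise ConfigError("config source must parse to a mapping")
    data.update(overrides)
    return config_from_dict(data)


def dump_config(config: ExperimentConfig) -> str:
    """YAML text round-trippable through :func:`load_config`."""
    return yaml.safe_dump(config_to_dict(config), sort_keys=True)
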