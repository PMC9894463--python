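"""End-of-day physiology: feed-conversion growth and allometric length.

The growth model is deliberately minimal: daily body-mass gain is the mass
of feed ingested times a feed conversion efficiency (FCE), applied once at
the end of each day, and total length follows from mass through the fitted
allometric power law ``W = a * TL**b`` (W in grams, TL in centimeters).
There is no maintenance or metabolic cost term, so mass never decreases;
zero intake leaves mass unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GrowthParams",
    "daily_growth",
    "length_from_mass",
    "mass_from_length",
    "smax_for_mass",
]


@dataclass(frozen=True)
class GrowthParams:
    fce: float = 1.0
    allometry_a: float = 0.0209   # g per cm**b
    allometry_b: float = 2.843
    smax_fraction: float = 0.04

    def __post_init__(self) -> None:
        for name in ("fce", "allometry_a", "allometry_b", "smax_fraction"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


def daily_growth(mass, intake, fce=1.0):
    """New body mass (g) after one day: ``W + S * FCE``.

    Accepts scalars or arrays; broadcasting follows numpy rules.
    """
    return np.asarray(mass, dtype=float) + np.asarray(intake, dtype=float) * fce


def length_from_mass(mass, a=0.0209, b=2.843):
    """Total length in centimeters from body mass in grams: ``(W/a)**(1/b)``."""
    mass = np.asarray(mass, dtype=float)
    if np.any(mass <= 0):
        raise ValueError("mass must be > 0")
    return (mass / a) ** (1.0 / b)


def mass_from_length(length_cm, a=0.0209, b=2.843):
    """Body mass in grams from total length in centimeters: ``a * TL**b``."""
    length_cm = np.asarray(length_cm, dtype=float)
    return a * length_cm ** b


def smax_for_mass(mass, smax_fraction=0.04):
    """Daily satiation cap in grams: a fixed fraction of body mass.

    The same operator serves the daily ration (a fraction of school
    biomass) since both are linear in mass.
    """
    return np.asarray(mass, dtype=float) * smax_fraction
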