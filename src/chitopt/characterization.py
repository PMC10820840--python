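"""Closed-form chitosan characterization conversions.

These formulas turn raw bench measurements into the three response variables
of the deacetylation study:

* potentiometric titration -> degree of deacetylation (DD, %),
* capillary viscometry + Mark-Houwink-Sakurada -> viscometric molar mass
  (M_v, reported in kDa),
* mass balance -> chitosan yield (%).

The DD conversion uses the acetyl quotient Q = C_M * dV / m (mol NaOH per
gram of sample, dV being the volume between the two titration inflection
points) and

    DD% = 100 * 203*Q / (1 + 42*Q)

with 203 g/mol the chitin monomer molar mass and 42 g/mol the acetyl group.
DD is monotone in Q and tends to 100*203/42 ~ 483 % as Q -> inf; values over
100 % are physically impossible and are flagged, never silently capped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TitrationMeasurement",
    "ViscometryMeasurement",
    "MassPair",
    "acetyl_quotient",
    "deacetylation_degree",
    "molar_mass_from_viscosity",
    "intrinsic_viscosity",
    "chitosan_yield",
    "MARK_HOUWINK_K",
    "MARK_HOUWINK_ALPHA",
]

#: chitin monomer molar mass, g/mol
CHITIN_MONOMER_G_MOL = 203.0
#: acetyl group molar mass, g/mol
ACETYL_G_MOL = 42.0
#: Mark-Houwink constant for chitosan in the study's solvent system, mL/g
MARK_HOUWINK_K = 13.8e-3
#: Mark-Houwink exponent, dimensionless
MARK_HOUWINK_ALPHA = 0.85


@dataclass(frozen=True)
class TitrationMeasurement:
    """NaOH titration of a dissolved chitosan sample.

    cm: titrant molarity (mol/L); dv: volume between the two inflection
    points (L); m: analyzed chitosan mass (g).
    """

    cm: float
    dv: float
    m: float

    def __post_init__(self) -> None:
        if self.cm <= 0:
            raise ValueError(f"titrant molarity must be > 0, got {self.cm}")
        if self.dv < 0:
            raise ValueError(f"inflection volume difference must be >= 0, got {self.dv}")
        if self.m <= 0:
            raise ValueError(f"sample mass must be > 0, got {self.m}")


@dataclass(frozen=True)
class ViscometryMeasurement:
    """Intrinsic viscosity (mL/g) with Mark-Houwink constants K (mL/g), alpha."""

    eta: float
    k: float = MARK_HOUWINK_K
    alpha: float = MARK_HOUWINK_ALPHA

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError(f"intrinsic viscosity must be >= 0, got {self.eta}")
        if self.k <= 0:
            raise ValueError(f"Mark-Houwink K must be > 0, got {self.k}")
        if not 0 < self.alpha <= 1.5:
            raise ValueError(f"Mark-Houwink alpha must be in (0, 1.5], got {self.alpha}")


@dataclass(frozen=True)
class MassPair:
    """Extracted chitosan and chitin masses in grams."""

    chitosan_g: float
    chitin_g: float

    def __post_init__(self) -> None:
        if self.chitin_g <= 0:
            raise ValueError(f"chitin mass must be > 0, got {self.chitin_g}")
        if self.chitosan_g < 0:
            raise ValueError(f"chitosan mass must be >= 0, got {self.chitosan_g}")


def acetyl_quotient(t: TitrationMeasurement) -> float:
    """Moles of NaOH consumed per gram of sample, Q = cm * dv / m."""
    return t.cm * t.dv / t.m


def deacetylation_degree(q: float) -> float:
    """Degree of deacetylation (%) from the acetyl quotient Q (mol/g).

    Warns (does not truncate) if the result exceeds the physical 100 % bound.
    """
    if q < 0:
        raise ValueError(f"acetyl quotient must be >= 0, got {q}")
    dd = 100.0 * CHITIN_MONOMER_G_MOL * q / (1.0 + ACETYL_G_MOL * q)
    if dd > 100.0:
        warnings.warn(
            f"DD = {dd:.2f}% exceeds the physical 100% bound; "
            "check the titration inputs",
            stacklevel=2,
        )
    return dd


def molar_mass_from_viscosity(v: ViscometryMeasurement) -> float:
    """Viscometric molar mass M_v (g/mol) by inverting [eta] = K * M_v^alpha."""
    if v.eta == 0:
        raise ValueError("intrinsic viscosity 0 gives an undefined molar mass")
    return float((v.eta / v.k) ** (1.0 / v.alpha))


def intrinsic_viscosity(mv: float, k: float = MARK_HOUWINK_K,
                        alpha: float = MARK_HOUWINK_ALPHA) -> float:
    """Forward Mark-Houwink relation [eta] = K * M_v^alpha (mL/g)."""
    if mv <= 0:
        raise ValueError(f"molar mass must be > 0, got {mv}")
    return float(k * mv**alpha)


def chitosan_yield(p: MassPair) -> float:
    """Chitosan extraction yield, 100 * chitosan_g / chitin_g (%)."""
    return 100.0 * p.chitosan_g / p.chitin_g


def mv_to_kda(mv_g_mol):
    """Convert a molar mass from g/mol to kDa (scalar or array)."""
    return mv_g_mol / 1000.0
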