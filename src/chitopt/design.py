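"""Central composite designs and coded/real factor transforms.

A rotatable central composite design (CCD) for k factors consists of a 2^k
full factorial block at coded levels ±1, 2k axial runs at coded ±alpha on
one axis at a time, and replicated centre runs at the coded origin.  Coded
value and physical value are related by the affine map

    coded = (real - center) / step,        real = center + step * coded,

so the factorial levels sit at ±1 and the centre at 0.  The default design
shipped here is the three-factor chitin-deacetylation layout: NaOH
concentration (centre 45 %, step 10), liquid:solid ratio (centre 18, step 5)
and process duration (centre 120 min, step 30 min), with axial magnitude
alpha = 1.68 and three centre replicates, 17 runs in total.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorDef",
    "DesignSpec",
    "build_ccd",
    "code_point",
    "decode_point",
    "deacetylation_design",
]


@dataclass(frozen=True)
class FactorDef:
    """One experimental factor and its coded-unit scaling.

    Parameters
    ----------
    name : str
        Column name used in design tables (e.g. ``"naoh_pct"``).
    unit : str
        Physical unit, for reporting only.
    center : float
        Real value at coded 0.
    step : float
        Real change corresponding to +1 coded unit; must be positive.
    axial_alpha : float
        Coded magnitude of the axial (star) runs; must be >= 1.
    """

    name: str
    unit: str
    center: float
    step: float
    axial_alpha: float = 1.68

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"factor {self.name!r}: step must be > 0, got {self.step}")
        if self.axial_alpha < 1:
            raise ValueError(
                f"factor {self.name!r}: axial_alpha must be >= 1, got {self.axial_alpha}"
            )

    def code(self, real: float) -> float:
        return (real - self.center) / self.step

    def decode(self, coded: float) -> float:
        return self.center + self.step * coded


@dataclass(frozen=True)
class DesignSpec:
    """An ordered set of factors plus the number of centre replicates."""

    factors: tuple[FactorDef, ...]
    n_center: int = 3

    def __post_init__(self) -> None:
        if len(self.factors) < 1:
            raise ValueError("DesignSpec needs at least one factor")
        if self.n_center < 0:
            raise ValueError("n_center must be >= 0")
        object.__setattr__(self, "factors", tuple(self.factors))

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        return 2**self.k + 2 * self.k + self.n_center

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]


def deacetylation_design(n_center: int = 3, axial_alpha: float = 1.68) -> DesignSpec:
    """The three-factor deacetylation CCD (NaOH %, liquid:solid ratio, minutes)."""
    return DesignSpec(
        factors=(
            FactorDef("naoh_pct", "%", 45.0, 10.0, axial_alpha),
            FactorDef("ratio", "mL/g", 18.0, 5.0, axial_alpha),
            FactorDef("duration_min", "min", 120.0, 30.0, axial_alpha),
        ),
        n_center=n_center,
    )


def build_ccd(spec: DesignSpec) -> pd.DataFrame:
    """Build the coded CCD run table in canonical order.

    Order is: the 2^k factorial block in standard Yates order (first factor
    cycling fastest), then the axial pair (-alpha, +alpha) for each factor in
    turn, then the centre replicates.  Columns are ``x1..xk``; the index is a
    1-based ``run_id``.
    """
    k = spec.k
    rows: list[list[float]] = []
    # Yates order: factor 1 alternates fastest
    for combo in itertools.product(*[(-1.0, 1.0)] * k):
        rows.append(list(combo[::-1]))
    for j, f in enumerate(spec.factors):
        for sign in (-1.0, 1.0):
            point = [0.0] * k
            point[j] = sign * f.axial_alpha
            rows.append(point)
    rows.extend([[0.0] * k] * spec.n_center)
    table = pd.DataFrame(rows, columns=[f"x{i + 1}" for i in range(k)])
    table.index = pd.RangeIndex(1, len(rows) + 1, name="run_id")
    return table


def _check_length(values, spec: DesignSpec, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape[-1] != spec.k:
        raise ValueError(
            f"{what} has {arr.shape[-1]} coordinates but the design has {spec.k} factors"
        )
    return arr


def code_point(real_values, spec: DesignSpec) -> np.ndarray:
    """Map real factor settings to coded coordinates, (real - center)/step."""
    arr = _check_length(real_values, spec, "real point")
    centers = np.array([f.center for f in spec.factors])
    steps = np.array([f.step for f in spec.factors])
    return (arr - centers) / steps


def decode_point(coded, spec: DesignSpec) -> np.ndarray:
    """Map coded coordinates back to real factor settings, center + step*coded."""
    arr = _check_length(coded, spec, "coded point")
    centers = np.array([f.center for f in spec.factors])
    steps = np.array([f.step for f in spec.factors])
    return centers + steps * arr


def real_view(table: pd.DataFrame, spec: DesignSpec) -> pd.DataFrame:
    """Append real-value columns (named per factor) to a coded design table."""
    out = table.copy()
    coded = table[[f"x{i + 1}" for i in range(spec.k)]].to_numpy()
    reals = decode_point(coded, spec)
    for j, f in enumerate(spec.factors):
        out[f.name] = reals[:, j]
    return out
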