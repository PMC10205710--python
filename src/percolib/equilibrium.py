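"""Equilibrium mass balances and packed-bed geometry.

The solid-liquid equilibrium of the extraction is described by a volume
partition coefficient ``D_is = C_s / C_w`` (solute concentration per unit
swollen-solid volume over that per unit liquid volume).  Together with a
total mass balance ``C_w V_w + C_s V_s = M0 m`` it yields both the
measurement formula for ``D_is`` and the soak-equilibrium liquid
concentration at the start of percolation.

Bed geometry: the swollen herb occupies the column according to an
expansion coefficient alpha (mL per g of dry herb), from which the bed
height H is predicted.  The source prints two mutually inconsistent
formulas relating alpha, H and the voidage; both are exposed via the
``mode`` argument of :func:`bed_height` (see its docstring).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._units import ML_PER_M3, circle_area

__all__ = [
    "MaterialBatch",
    "BedSpec",
    "EquilibriumMeasurement",
    "volume_partition_coefficient",
    "average_dis",
    "initial_concentration",
    "relative_error",
    "expansion_coefficient",
    "bed_height",
    "DIS_POOLED_DEFAULT",
]

#: Pooled volume partition coefficient used for prediction on new batches
#: (the fixed value adopted for design-space work).
DIS_POOLED_DEFAULT = 1.21


@dataclass(frozen=True)
class MaterialBatch:
    """Per-batch herb properties.

    M0: extractable marker content, mg per g dry herb.
    D_is: volume partition coefficient (dimensionless).
    D_eff: apparent intra-particle diffusivity, m^2/min.
    particle_size: characteristic (mesh-opening) size, m.
    """

    M0: float
    D_is: float
    D_eff: float
    particle_size: float
    mesh_class: str | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.M0 < 0:
            raise ValueError("M0 must be >= 0")
        if self.D_is <= 0:
            raise ValueError("D_is must be > 0")
        if self.D_eff <= 0:
            raise ValueError("D_eff must be > 0")
        if self.particle_size <= 0:
            raise ValueError("particle_size must be > 0")

    @property
    def particle_radius(self) -> float:
        """Sphere radius used for specific surface and internal transfer, m."""
        return self.particle_size / 2.0


@dataclass(frozen=True)
class BedSpec:
    """Column geometry and process settings.

    column_diameter in m, herb_mass in g, voidage dimensionless in (0, 1),
    expansion_coefficient in mL/g, bed_height in m (may be derived),
    flow_rate in mL/min, inlet_concentration in mg/mL.
    """

    column_diameter: float
    herb_mass: float
    voidage: float
    expansion_coefficient: float
    flow_rate: float
    bed_height: float | None = None
    inlet_concentration: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.voidage < 1.0:
            raise ValueError("voidage must lie in (0, 1)")
        for name in ("column_diameter", "herb_mass", "flow_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.bed_height is not None and self.bed_height <= 0:
            raise ValueError("bed_height must be > 0")
        if self.inlet_concentration < 0:
            raise ValueError("inlet_concentration must be >= 0")

    @property
    def cross_section(self) -> float:
        """Column cross-sectional area, m^2."""
        return circle_area(self.column_diameter)

    def height(self, mode: str = "as_printed") -> float:
        """Bed height, m: explicit value if set, else from alpha (Eq-based)."""
        if self.bed_height is not None:
            return self.bed_height
        return bed_height(
            self.herb_mass,
            self.expansion_coefficient,
            self.voidage,
            self.column_diameter,
            mode=mode,
        )

    def bed_volume_ml(self, mode: str = "as_printed") -> float:
        return self.cross_section * self.height(mode) * ML_PER_M3


@dataclass(frozen=True)
class EquilibriumMeasurement:
    """One shake-flask equilibrium measurement.

    C_w mg/mL, V_w and V_s in mL, m in g, M0 in mg/g.
    """

    C_w: float
    V_w: float
    V_s: float
    m: float
    M0: float

    def __post_init__(self) -> None:
        if self.V_w <= 0:
            raise ValueError("V_w must be > 0")
        for name in ("C_w", "V_s", "m", "M0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def volume_partition_coefficient(meas: EquilibriumMeasurement) -> float:
    """D_is from a closed mass balance: (M0 m / C_w - V_w) / V_s.

    A negative result means the measured solution holds more solute than the
    total balance allows -- an inconsistent measurement -- and raises.
    """
    if meas.C_w <= 0:
        raise ValueError("C_w must be > 0 to infer a partition coefficient")
    if meas.V_s <= 0:
        raise ValueError("V_s must be > 0")
    dis = (meas.M0 * meas.m / meas.C_w - meas.V_w) / meas.V_s
    if dis < 0:
        raise ValueError(
            f"inconsistent measurement: implied D_is = {dis:.4g} < 0 "
            "(solution holds more solute than the mass balance allows)"
        )
    return dis


def average_dis(values: Iterable[float]) -> float:
    """Batch-mean partition coefficient, rounded to 2 decimals (table convention)."""
    vals = list(values)
    if not vals:
        raise ValueError("empty D_is list")
    return round(float(np.mean(vals)), 2)


def initial_concentration(M0: float, m: float, D_is: float, V_s: float, V_w: float) -> float:
    """Soak-equilibrium liquid concentration C_w^0 = M0 m / (D_is V_s + V_w), mg/mL."""
    denom = D_is * V_s + V_w
    if denom <= 0:
        raise ValueError("D_is*V_s + V_w must be > 0")
    return M0 * m / denom


def relative_error(predicted: float, observed: float) -> float:
    """|predicted - observed| / observed * 100, percent."""
    if observed == 0:
        raise ValueError("observed must be nonzero")
    return abs(predicted - observed) / abs(observed) * 100.0


def expansion_coefficient(d: float, h_bed: float, voidage: float, m: float) -> float:
    """Expansion coefficient alpha = pi d^2 h eps / (4 m), mL per g of herb.

    ``d`` and ``h_bed`` in metres, ``m`` in grams.
    """
    if m <= 0:
        raise ValueError("herb mass must be > 0")
    if d <= 0 or h_bed < 0 or voidage < 0:
        raise ValueError("d must be > 0 and h, voidage >= 0")
    return circle_area(d) * h_bed * voidage / m * ML_PER_M3


def bed_height(m: float, alpha: float, voidage: float, d: float, mode: str = "as_printed") -> float:
    """Predicted bed height, metres.

    mode='as_printed'      H = 4 m alpha / ((1 - eps) pi d^2)
    mode='eq17_consistent' H = 4 m alpha / (eps pi d^2)  (exact inverse of
    :func:`expansion_coefficient`).

    The two printed relations between alpha and H disagree (one divides by
    the voidage, the other by the solid fraction).  The default is the
    printed height formula: it is the reading under which the model's
    endpoint predictions land on the validation measurements, and it is the
    physically coherent one if alpha is the swollen-solid volume per gram.
    ``eq17_consistent`` exists for exact alpha <-> H round trips.
    """
    if m < 0 or alpha < 0:
        raise ValueError("m and alpha must be >= 0")
    if d <= 0:
        raise ValueError("d must be > 0")
    if not 0.0 < voidage < 1.0:
        raise ValueError("voidage must lie in (0, 1)")
    alpha_m3 = alpha / ML_PER_M3
    if mode == "as_printed":
        return 4.0 * m * alpha_m3 / ((1.0 - voidage) * math.pi * d**2)
    if mode == "eq17_consistent":
        return 4.0 * m * alpha_m3 / (voidage * math.pi * d**2)
    raise ValueError("mode must be 'as_printed' or 'eq17_consistent'")
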