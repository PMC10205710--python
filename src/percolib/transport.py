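"""Mass-transfer and axial-dispersion correlation library.

External film coefficients (five literature correlations), the internal
coefficient k_int = 5 D_eff / r_p, their series combination
K_x = [1/k_int + 1/k_ext]^-1, and five axial dispersion correlations.

Conventions (fixed by reproducing the source's Ruthven dispersion values
and its internal-coefficient table):

* the velocity entering every correlation is the *interstitial* velocity
  u = Q / (A eps);
* the particle size ``r`` entering Re, Sh, Pe and the dispersion formulas
  is the full mean sieve-opening size (e.g. 1.425 mm for 10-24 mesh);
* the internal coefficient instead uses the sphere *radius* r_p = r/2.

Dimensionless groups are formed in SI; coefficients are reported in
metres/minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, NamedTuple

from ._units import (
    DM_SAB_WATER,
    WATER_DENSITY,
    WATER_VISCOSITY,
    m_per_min_to_m_per_s,
    m_per_s_to_m_per_min,
    m2_per_s_to_m2_per_min,
    circle_area,
)

__all__ = [
    "FluidProperties",
    "TransportParams",
    "WATER_25C",
    "KEXT_CORRELATIONS",
    "DAX_CORRELATIONS",
    "superficial_velocity",
    "interstitial_velocity",
    "dimensionless_groups",
    "internal_mass_transfer",
    "external_mass_transfer",
    "axial_dispersion",
    "combine_kx",
    "wilke_chang_diffusivity",
    "derive_transport",
]


@dataclass(frozen=True)
class FluidProperties:
    """Solvent properties: density kg/m^3, viscosity Pa.s, D_m m^2/s."""

    density: float = WATER_DENSITY
    viscosity: float = WATER_VISCOSITY
    molecular_diffusivity: float = DM_SAB_WATER

    def __post_init__(self) -> None:
        for name in ("density", "viscosity", "molecular_diffusivity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


#: Water at 25 C with the solute's reported molecular diffusivity.
WATER_25C = FluidProperties()


@dataclass(frozen=True)
class TransportParams:
    """Bundle of transport coefficients entering the percolation PDE.

    k_int, k_ext, K_x in m/min; D_ax in m^2/min.  The correlation names
    that produced k_ext / D_ax are carried along for provenance.
    """

    k_int: float
    k_ext: float
    K_x: float
    D_ax: float
    kext_correlation: str | None = None
    dax_correlation: str | None = None

    def __post_init__(self) -> None:
        for name in ("k_int", "k_ext", "K_x", "D_ax"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.K_x > min(self.k_int, self.k_ext) * (1 + 1e-12):
            raise ValueError("K_x cannot exceed either film coefficient")


class Groups(NamedTuple):
    Re: float
    Sc: float
    Pe: float


def superficial_velocity(Q_ml_min: float, d: float) -> float:
    """Superficial (empty-column) velocity, m/min, from pump flow mL/min."""
    if d <= 0:
        raise ValueError("column diameter must be > 0")
    if Q_ml_min < 0:
        raise ValueError("flow must be >= 0")
    return (Q_ml_min * 1e-6) / circle_area(d)


def interstitial_velocity(u_s: float, voidage: float) -> float:
    """Interstitial velocity u = u_s / eps, m/min."""
    if not 0.0 < voidage <= 1.0:
        raise ValueError("voidage must lie in (0, 1]")
    if u_s < 0:
        raise ValueError("u_s must be >= 0")
    return u_s / voidage


def dimensionless_groups(fluid: FluidProperties, u: float, r: float) -> Groups:
    """(Re, Sc, Pe) with Re = 2 rho u r / mu, Sc = mu/(rho D_m), Pe = Re Sc.

    ``u`` is the interstitial velocity in m/min (converted to SI here),
    ``r`` the particle size in m.  Pe reduces to 2 u r / D_m, independent
    of density and viscosity.
    """
    if u < 0 or r <= 0:
        raise ValueError("u must be >= 0 and r > 0")
    u_si = m_per_min_to_m_per_s(u)
    Re = 2.0 * fluid.density * u_si * r / fluid.viscosity
    Sc = fluid.viscosity / (fluid.density * fluid.molecular_diffusivity)
    return Groups(Re=Re, Sc=Sc, Pe=Re * Sc)


def internal_mass_transfer(D_eff: float, r_p: float) -> float:
    """Internal (intra-particle) coefficient k_int = 5 D_eff / r_p, m/min.

    ``r_p`` is the particle *radius* (half the sieve-opening size).
    """
    if r_p <= 0:
        raise ValueError("particle radius must be > 0")
    if D_eff < 0:
        raise ValueError("D_eff must be >= 0")
    return 5.0 * D_eff / r_p


def _sh_to_kext(Sh: float, fluid: FluidProperties, r: float) -> float:
    """k_ext = Sh D_m / (2 r), converted to m/min."""
    return m_per_s_to_m_per_min(Sh * fluid.molecular_diffusivity / (2.0 * r))


def _kext_vermeulen(fluid, u, r, eps):
    # k_ext = 5.21 (D_m u0)^0.5 r / (6 (2r)^1.5 (1 - eps)), evaluated in SI
    u_si = m_per_min_to_m_per_s(u)
    k = 5.21 * math.sqrt(fluid.molecular_diffusivity * u_si) * r / (
        6.0 * (2.0 * r) ** 1.5 * (1.0 - eps)
    )
    return m_per_s_to_m_per_min(k)


def _kext_williamson(fluid, u, r, eps):
    # k_ext = 2.4 u0 Re^-0.66 Sc^-0.58
    Re, Sc, _ = dimensionless_groups(fluid, u, r)
    if Re == 0:
        return 0.0
    u_si = m_per_min_to_m_per_s(u)
    return m_per_s_to_m_per_min(2.4 * u_si * Re**-0.66 * Sc**-0.58)


def _kext_wilson_geankoplis(fluid, u, r, eps):
    Re, Sc, _ = dimensionless_groups(fluid, u, r)
    Sh = 1.09 / eps * (Re * Sc) ** (1.0 / 3.0)
    return _sh_to_kext(Sh, fluid, r)


def _kext_ranz_marshall(fluid, u, r, eps):
    Re, Sc, _ = dimensionless_groups(fluid, u, r)
    Sh = 2.0 + 0.6 * Sc ** (1.0 / 3.0) * Re**0.5
    return _sh_to_kext(Sh, fluid, r)


def _kext_wakao_funazkri(fluid, u, r, eps):
    Re, Sc, _ = dimensionless_groups(fluid, u, r)
    Sh = 2.0 + 1.1 * Sc ** (1.0 / 3.0) * Re**0.6
    return _sh_to_kext(Sh, fluid, r)


#: Registry order is the declaration order used for deterministic tie-breaks.
KEXT_CORRELATIONS: dict[str, Callable] = {
    "vermeulen": _kext_vermeulen,
    "williamson": _kext_williamson,
    "wilson_geankoplis": _kext_wilson_geankoplis,
    "ranz_marshall": _kext_ranz_marshall,
    "wakao_funazkri": _kext_wakao_funazkri,
}


def external_mass_transfer(
    name: str,
    fluid: FluidProperties,
    u: float,
    r: float,
    voidage: float,
) -> float:
    """External film coefficient by named correlation, m/min.

    ``u`` is the interstitial velocity (m/min); ``r`` the mean sieve-opening
    size (m).  Sherwood-based forms are converted via k_ext = Sh D_m / (2 r).
    """
    try:
        fn = KEXT_CORRELATIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown k_ext correlation {name!r}; choose from {list(KEXT_CORRELATIONS)}"
        ) from None
    if u < 0 or r <= 0 or not 0 < voidage < 1:
        raise ValueError("require u >= 0, r > 0, 0 < voidage < 1")
    return fn(fluid, u, r, voidage)


def _dm_m2_min(fluid: FluidProperties) -> float:
    return m2_per_s_to_m2_per_min(fluid.molecular_diffusivity)


def _dax_chung_wen(fluid, u, r, eps):
    Re, _, _ = dimensionless_groups(fluid, u, r)
    if u == 0:
        return 0.0
    return 2.0 * r * eps * u / (0.2 + 0.011 * Re**0.48)


def _dax_athayle(fluid, u, r, eps):
    _, _, Pe = dimensionless_groups(fluid, u, r)
    if u == 0:
        return 0.0
    return 2.0 * u * r * (Pe / (1.0 - eps)) ** (1.0 / 6.0)


def _dax_koch_brady(fluid, u, r, eps):
    # eps_b (undefined in the source) is taken equal to the bed voidage.
    _, _, Pe = dimensionless_groups(fluid, u, r)
    if u == 0:
        return 0.0
    bracket = 0.75 + math.pi**2 / 6.0 * (1.0 - eps) * math.log(Pe) + 1.0 / Pe
    return 2.0 * r * u * eps * bracket


def _dax_gunn(fluid, u, r, eps):
    Re, _, Pe = dimensionless_groups(fluid, u, r)
    if u == 0:
        return 0.0
    Z = Pe / (23.1361 * (1.0 - eps))
    p = 0.17 + 0.33 * math.exp(-24.0 / Re)
    zp = Z * p * (1.0 - p)
    ratio = (
        2.0 * Z * (1.0 - p) ** 2
        - Z**2 * p * (1.0 - p) ** 3 * (1.0 - math.exp(-1.0 / zp))
        + eps / (1.4 * Pe)
    )
    return ratio * u * r


def _dax_ruthven(fluid, u, r, eps):
    return 0.5 * _dm_m2_min(fluid) + 1.4 * r * u


DAX_CORRELATIONS: dict[str, Callable] = {
    "chung_wen": _dax_chung_wen,
    "athayle": _dax_athayle,
    "koch_brady": _dax_koch_brady,
    "gunn": _dax_gunn,
    "ruthven": _dax_ruthven,
}


def axial_dispersion(
    name: str,
    fluid: FluidProperties,
    u: float,
    r: float,
    voidage: float,
) -> float:
    """Axial dispersion coefficient by named correlation, m^2/min.

    Same velocity/size conventions as :func:`external_mass_transfer`.
    At u = 0 the flow-driven correlations return 0; Ruthven returns its
    molecular limit 0.5 D_m.
    """
    try:
        fn = DAX_CORRELATIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown D_ax correlation {name!r}; choose from {list(DAX_CORRELATIONS)}"
        ) from None
    if u < 0 or r <= 0 or not 0 < voidage < 1:
        raise ValueError("require u >= 0, r > 0, 0 < voidage < 1")
    return fn(fluid, u, r, voidage)


def combine_kx(k_int: float, k_ext: float) -> float:
    """Series (two-film) combination [1/k_int + 1/k_ext]^-1, m/min."""
    if k_int <= 0 or k_ext <= 0:
        raise ValueError("film coefficients must be > 0")
    return 1.0 / (1.0 / k_int + 1.0 / k_ext)


def wilke_chang_diffusivity(
    T: float,
    mu: float,
    solvent_assoc: float = 2.6,
    M_solvent: float = 18.015,
    V_molar: float = 500.0,
) -> float:
    """Wilke-Chang estimate of a solute's molecular diffusivity, m^2/s.

    D = 7.4e-8 (phi M)^0.5 T / (mu_cP V^0.6) in cm^2/s, converted to m^2/s.
    ``T`` in K, ``mu`` in Pa.s, ``V_molar`` the solute molar volume at the
    normal boiling point, cm^3/mol.  Provided as a convenience estimator;
    the package default is the reported constant 5.83e-10 m^2/s
    (:data:`percolib._units.DM_SAB_WATER`).
    """
    if T <= 0 or mu <= 0 or solvent_assoc <= 0 or M_solvent <= 0 or V_molar <= 0:
        raise ValueError("all Wilke-Chang inputs must be > 0")
    mu_cp = mu * 1000.0
    d_cm2_s = 7.4e-8 * math.sqrt(solvent_assoc * M_solvent) * T / (mu_cp * V_molar**0.6)
    return d_cm2_s * 1e-4


def derive_transport(
    material,
    bed,
    fluid: FluidProperties = WATER_25C,
    kext_name: str = "wilson_geankoplis",
    dax_name: str = "koch_brady",
) -> TransportParams:
    """Compute the full transport bundle for a material/bed combination.

    Uses the interstitial velocity and the module's particle-size
    conventions; the default correlation pair is the one selected by the
    screening procedure.
    """
    u_s = superficial_velocity(bed.flow_rate, bed.column_diameter)
    u = interstitial_velocity(u_s, bed.voidage)
    k_int = internal_mass_transfer(material.D_eff, material.particle_radius)
    k_ext = external_mass_transfer(kext_name, fluid, u, material.particle_size, bed.voidage)
    d_ax = axial_dispersion(dax_name, fluid, u, material.particle_size, bed.voidage)
    return TransportParams(
        k_int=k_int,
        k_ext=k_ext,
        K_x=combine_kx(k_int, k_ext),
        D_ax=d_ax,
        kext_correlation=kext_name,
        dax_correlation=dax_name,
    )
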