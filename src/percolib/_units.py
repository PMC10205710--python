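"""Unit conversions and shared physical constants.

Internal discipline: dimensionless groups are formed in SI (m, s, kg);
reported transport coefficients use metres and minutes; concentrations are
mg/mL (equal to mg/g for dilute aqueous extracts, density ~ 1 g/mL);
volumetric flows are mL/min.
"""

S_PER_MIN = 60.0
ML_PER_M3 = 1.0e6
M3_PER_ML = 1.0e-6

#: Molecular diffusivity of salvianolic acid B in water at 25 C, m^2/s.
#: Wilke-Chang estimate reported by the source data set; used as the
#: default everywhere a D_m is needed.
DM_SAB_WATER = 5.83e-10

#: Water at 25 C.
WATER_DENSITY = 1000.0       # kg/m^3
WATER_VISCOSITY = 8.9e-4     # Pa.s


def m2_per_s_to_m2_per_min(x: float) -> float:
    return x * S_PER_MIN


def m_per_s_to_m_per_min(x: float) -> float:
    return x * S_PER_MIN


def m_per_min_to_m_per_s(x: float) -> float:
    return x / S_PER_MIN


def circle_area(diameter_m: float) -> float:
    """Cross-sectional area of the column, m^2."""
    import math

    return math.pi * diameter_m**2 / 4.0
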