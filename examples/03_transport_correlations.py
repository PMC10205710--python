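"""Transport coefficients for the reference percolation experiment.

Computes the dimensionless groups and every registered external-transfer
and axial-dispersion correlation for the reference conditions (2 mL/min,
5 cm column, voidage 0.41, 10-24 mesh particles), then combines the film
coefficients into the overall K_x.
"""

import percolib as pl
from percolib.transport import DAX_CORRELATIONS, KEXT_CORRELATIONS, WATER_25C

FLOW, D_COL, EPS, R = 2.0, 0.05, 0.41, 1.425e-3

u_s = pl.superficial_velocity(FLOW, D_COL)
u = pl.interstitial_velocity(u_s, EPS)
groups = pl.dimensionless_groups(WATER_25C, u, R)
print(f"superficial velocity  u_s = {u_s:.4g} m/min")
print(f"interstitial velocity u   = {u:.4g} m/min")
print(f"Re = {groups.Re:.4g}   Sc = {groups.Sc:.6g}   Pe = {groups.Pe:.5g}")

k_int = pl.internal_mass_transfer(1.089e-8, R / 2)
print(f"\ninternal coefficient k_int = {k_int:.3g} m/min (pooled D_eff, radius r/2)")

print("\nexternal film coefficients, m/min:")
for name in KEXT_CORRELATIONS:
    k = pl.external_mass_transfer(name, WATER_25C, u, R, EPS)
    print(f"  {name:<18} {k:.3g}")

print("\naxial dispersion coefficients, m^2/min:")
for name in DAX_CORRELATIONS:
    d = pl.axial_dispersion(name, WATER_25C, u, R, EPS)
    print(f"  {name:<18} {d:.3g}")

k_ext = pl.external_mass_transfer("wilson_geankoplis", WATER_25C, u, R, EPS)
print(f"\ncombined K_x = {pl.combine_kx(k_int, k_ext):.3g} m/min (series resistances;")
print("always below the smaller film coefficient).")
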