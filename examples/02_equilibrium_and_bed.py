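"""Equilibrium partition coefficient, initial concentration, bed geometry.

Walks one shake-flask equilibrium measurement to a volume partition
coefficient, predicts the soak-equilibrium concentration at the start of
percolation, and derives the bed height from the expansion coefficient.
"""

from percolib import (
    EquilibriumMeasurement,
    bed_height,
    expansion_coefficient,
    initial_concentration,
    relative_error,
    volume_partition_coefficient,
)

# A measurement: 50 g herb at 20 mg/g soaked; at equilibrium the 100 mL of
# solution assays 8 mg/mL and the swollen solid occupies 20 mL.
meas = EquilibriumMeasurement(C_w=8.0, V_w=100.0, V_s=20.0, m=50.0, M0=20.0)
dis = volume_partition_coefficient(meas)
print(f"volume partition coefficient D_is = {dis:.3g}  (solid-phase conc / liquid conc)")

cw0 = initial_concentration(M0=20.0, m=50.0, D_is=dis, V_s=20.0, V_w=100.0)
print(f"predicted soak-equilibrium concentration C_w0 = {cw0:.3g} mg/mL")
print(f"relative error vs the measured 8 mg/mL: {relative_error(cw0, meas.C_w):.2g}%")

# Bed geometry for 50 g in a 5 cm column at the pooled voidage 0.37
alpha = expansion_coefficient(d=0.05, h_bed=0.2416, voidage=0.41, m=50.0)
print(f"\nexpansion coefficient from a measured bed: alpha = {alpha:.3g} mL/g")
H = bed_height(m=50.0, alpha=3.81, voidage=0.37, d=0.05)
print(f"predicted bed height (50 g, alpha=3.81, eps=0.37): H = {H:.4g} m")
print("\nC_w0 closes the mass balance exactly: the column initially holds M0*m.")
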