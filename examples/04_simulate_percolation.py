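"""Simulate the reference percolation experiment end to end.

Builds the reference run from the built-in tables (batch D4, 10-24 mesh,
50 g, 2 mL/min), simulates 300 min and reports the effluent behaviour,
the collected yield and the solver's mass-balance drift.
"""

import percolib as pl

material = pl.material_from_batch("D4", "10-24")
bed = pl.bed_from_experiment("E1")
config = pl.make_config(material, bed, duration=300.0, n_cells=200)

print(f"bed height H = {config.bed_height_m:.4g} m, "
      f"initial concentration C_w0 = {config.initial_liquid_concentration:.4g} mg/mL")
tp = config.transport
print(f"K_x = {tp.K_x:.3g} m/min ({tp.kext_correlation}), "
      f"D_ax = {tp.D_ax:.3g} m^2/min ({tp.dax_correlation})")

result = pl.simulate_percolation(config)
for t in (0, 60, 120, 180, 240, 300):
    i = int(t / config.duration * (len(result.times) - 1))
    print(f"  t = {result.times[i]:5.0f} min   effluent = "
          f"{result.effluent_concentration[i]:7.4f} mg/mL   "
          f"yield = {result.cumulative_yield[i]:7.1f} mg")

total = material.M0 * bed.herb_mass
print(f"\ncollected {result.cumulative_yield[-1]:.0f} mg of the {total:.0f} mg "
      f"({100 * result.cumulative_yield[-1] / total:.1f}%) loaded")
print(f"mass-balance drift: {result.mass_balance_error:.2e} (fraction of inventory)")
print("\nThe effluent holds its soak-equilibrium plateau until the retained")
print("washout front reaches the outlet, then decays through a dispersed tail.")
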