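"""Screen external-transfer x dispersion correlation pairs.

Generates synthetic effluent curves for three experiments under a known
correlation pair, then checks that pairwise screening recovers it from
the 5x5 average-R^2 grid.
"""

import percolib as pl
from percolib.screening import screen_correlation_pairs, select_best_pair

TRUE_PAIR = ("wilson_geankoplis", "koch_brady")

experiments = []
for exp_id in ("E1", "E4", "E6"):
    fx = pl.builtin_fixtures().experiments[exp_id]
    material = pl.material_from_batch(fx.batch_id, fx.mesh_class)
    bed = pl.bed_from_experiment(exp_id)
    config = pl.make_config(
        material, bed, kext_name=TRUE_PAIR[0], dax_name=TRUE_PAIR[1],
        duration=300.0, n_cells=60, n_out=121,
    )
    experiments.append(pl.gen_percolation_experiment(config, noise_sd=0.05, seed=3))

result = screen_correlation_pairs(experiments)
print("average R^2 grid (rows: D_ax, columns: k_ext):")
print(result.grid.round(4).to_string())
kext, dax = select_best_pair(result)
print(f"\nselected pair: k_ext = {kext}, D_ax = {dax}")
print(f"generating pair was:  {TRUE_PAIR[0]}, {TRUE_PAIR[1]}")
print("\nOn self-generated data the generating pair attains the grid maximum;")
print("with 5% measurement noise it should still rank first.")
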