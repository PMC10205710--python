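"""Monte-Carlo sensitivity of the prediction quality to parameter errors.

Perturbs the six model parameters (voidage, particle size, partition
coefficient, film coefficients, dispersion) uniformly within their
measurement-error intervals and correlates each with the prediction R^2
against a pseudo-experimental reference curve.
"""

import percolib as pl
from percolib.transport import TransportParams, combine_kx
from percolib.uncertainty import sensitivity_analysis

# reference-experiment transport estimates
k_int, k_ext, d_ax = 7.64e-5, 2.20e-3, 4.89e-6
tp = TransportParams(k_int, k_ext, combine_kx(k_int, k_ext), d_ax)
bed = pl.bed_from_experiment("E1")

# pseudo-experimental reference: its true partition coefficient (1.10) sits
# below the pooled value 1.21 assumed by the model, as the published scatter
# analysis indicates for the measured curve
mat_true = pl.material_from_batch("D4", "10-24", D_is=1.10)
cfg_true = pl.make_config(mat_true, bed, tp, n_cells=80, duration=300.0, n_out=151)
_, reference = pl.gen_percolation_experiment(cfg_true, noise_sd=0.05, seed=7)

mat_base = pl.material_from_batch("D4", "10-24", D_is=1.21)
base = pl.make_config(mat_base, bed, tp, n_cells=80, duration=300.0, n_out=151)

result = sensitivity_analysis(base, reference=reference, n=500, seed=42)
print(result.correlations.round(3).to_string())
print(f"\ndominant parameter: {result.dominant_parameter()}")
print("\nA strongly negative partition-coefficient correlation means that")
print("overestimating solute retention in the solid degrades the prediction")
print("most; the other parameters' errors matter far less.")
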