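# percolib

Mechanistic modelling of **percolation extraction** — the continuous flow of
solvent through a packed bed of ground herbal material, collecting extract at
the outlet. The library targets process development for heat-labile,
water-soluble marker compounds (the motivating system is salvianolic acid B
extracted from *Salvia miltiorrhiza* root), where percolation is preferred
over hot extraction and the practical questions are: *when is the bed
exhausted, how much is collected, and which operating conditions meet a
quality target robustly?*

## The model

The column is a 1-D two-phase packed bed of height $H$. The liquid-phase
concentration $C_w(z,t)$ and solid-phase concentration $C_s(z,t)$ (per unit
swollen-solid volume) obey

$$
\frac{\partial C_w}{\partial t}
  = -u\,\frac{\partial C_w}{\partial z}
  + D_{ax}\frac{\partial^2 C_w}{\partial z^2}
  + \frac{3}{r_p}\,\frac{1-\varepsilon}{\varepsilon}\,
    K_x\!\left(\frac{C_s}{D_{is}} - C_w\right),
\qquad
\frac{\partial C_s}{\partial t}
  = \frac{3}{r_p}\,K_x\!\left(C_w - \frac{C_s}{D_{is}}\right)
$$

with interstitial velocity $u = Q/(A\varepsilon)$, bed voidage
$\varepsilon$, particle radius $r_p$, linear partition coefficient
$D_{is} = C_s/C_w$ at equilibrium, axial dispersion $D_{ax}$, and a two-film
mass-transfer coefficient $K_x = [1/k_{int} + 1/k_{ext}]^{-1}$ where
$k_{int} = 5 D_{eff}/r_p$ comes from impregnation (soaking) kinetics and
$k_{ext}$ from a packed-bed Sherwood correlation. The initial state is soak
equilibrium, so the column holds exactly $M_0 m$ of solute; the inlet feeds
clean solvent.

Around the solver the package provides:

- **impregnation kinetics** — first-order, Peleg and sphere-diffusion models
  with bounded least-squares fitting, yielding the apparent diffusivity
  $D_{eff}$;
- **equilibrium & bed** — partition-coefficient measurement, soak-equilibrium
  initial concentration, expansion-coefficient/bed-height relations;
- **transport correlations** — five $k_{ext}$ and five $D_{ax}$ literature
  correlations behind one registry;
- **correlation screening** — all 25 pairs scored by average $R^2$ against
  observed effluent curves;
- **uncertainty** — Monte-Carlo sensitivity analysis and a probabilistic
  design space (probability of meeting an endpoint-concentration and yield
  specification under production disturbances);
- **synthetic data** — noisy soaking/effluent curves with known ground truth,
  plus the published batch/experiment parameter tables as built-in fixtures.

## Worked example

Simulate the reference experiment (batch D4, 10–24 mesh, 50 g, 2 mL/min in a
5 cm column) straight from the built-in tables:

```python
import percolib as pl

material = pl.material_from_batch("D4", "10-24")
bed = pl.bed_from_experiment("E1")
config = pl.make_config(material, bed, duration=300.0, n_cells=200)
result = pl.simulate_percolation(config)
```

Running `python examples/04_simulate_percolation.py` prints:

```
bed height H = 0.1679 m, initial concentration C_w0 = 6.456 mg/mL
K_x = 5.52e-05 m/min (wilson_geankoplis), D_ax = 1.72e-05 m^2/min (koch_brady)
  t =     0 min   effluent =  6.4563 mg/mL   yield =     0.0 mg
  t =    60 min   effluent =  6.4407 mg/mL   yield =   774.5 mg
  t =   120 min   effluent =  5.6572 mg/mL   yield =  1517.1 mg
  t =   180 min   effluent =  3.3723 mg/mL   yield =  2066.3 mg
  t =   240 min   effluent =  1.3797 mg/mL   yield =  2341.0 mg
  t =   300 min   effluent =  0.4358 mg/mL   yield =  2440.9 mg

collected 2441 mg of the 2480 mg (98.4%) loaded
mass-balance drift: 2.80e-06 (fraction of inventory)
```

The effluent holds its soak-equilibrium plateau (6.46 mg/mL) until the
retained washout front — travelling at $u/(1 + (1-\varepsilon)D_{is}/\varepsilon)$
— reaches the outlet, then decays through a dispersion-broadened tail; the
yield approaches the loaded $M_0 m$ and the solver conserves mass to a few
parts per million.

The other scripts in `examples/` each demonstrate one capability (kinetic
fitting, transport correlations, screening, sensitivity, design space,
quantitative extraction / endpoint prediction). A thin CLI mirrors them:
`percolib simulate --config run.yaml --out effluent.csv`, plus
`fit-kinetics`, `dis`, `screen`, `sensitivity`, `design-space`,
`yield-window`, `endpoint`, `correlations list` and `fixtures export`.

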