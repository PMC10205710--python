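"""Monte-Carlo sensitivity analysis and probabilistic design space.

Sensitivity: the six model parameters (voidage, particle size, partition
coefficient, internal/external film coefficients, axial dispersion) are
drawn uniformly within measurement-error intervals; each draw is
simulated and scored (R^2) against a reference effluent curve; the
per-parameter Pearson correlation between draw and score measures how
strongly that parameter's error degrades the prediction.

Design space: over a grid of material properties and process parameters
(particle size, flow, herb mass, marker content), each cell is simulated
``n_reps`` times under production-disturbance perturbations; a replicate
passes if the effluent concentration at the evaluation horizon is below
the endpoint threshold and the cumulative yield exceeds the yield target.
Cells whose pass probability reaches the acceptance threshold form the
design space.

The evaluation horizon defaults to 400 min.  The retained washout front
of the reference operating point (50 g, 2 mL/min) leaves the column at
about 280-330 min, and a flow disturbance of -0.3 mL/min stretches that
by a factor 2.0/1.7; any horizon below ~325 min would therefore reject
the nominal operating point itself, while horizons beyond ~450 min no
longer discriminate against the slow, coarse-particle conditions.  See
docs/methods.md for the derivation.

Derived quantities (bed height, initial soak concentration, interstitial
velocity) are recomputed from each perturbed draw so every replicate is
internally mass-consistent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .curves import ConcentrationCurve
from .equilibrium import BedSpec, MaterialBatch
from .simulate import (
    PercolationResult,
    SimulationConfig,
    SimulationError,
    endpoint_time,
    make_config,
    r_squared,
    simulate_percolation,
)
from .transport import TransportParams, combine_kx, internal_mass_transfer

__all__ = [
    "PerturbationSpec",
    "SensitivityResult",
    "DesignSpaceTargets",
    "DesignSpaceResult",
    "sensitivity_analysis",
    "design_space",
    "predict_yield_window",
    "predict_endpoint",
]

#: Measurement-error half-widths for the sensitivity study (units of each
#: parameter), as tabulated for the reference experiment.
SENSITIVITY_HALFWIDTHS = {
    "voidage": 0.05,
    "r": 0.5e-3,
    "D_is": 0.10,
    "k_int": 1.00e-5,
    "k_ext": 1.00e-3,
    "D_ax": 1.00e-6,
}

#: Production-disturbance half-widths for design-space work.
DESIGN_HALFWIDTHS = {
    "r": 0.0001,
    "flow": 0.3,
    "mass": 0.5,
    "M0": 1.0,
}

_TINY = 1e-9


@dataclass(frozen=True)
class PerturbationSpec:
    """Uniform disturbance intervals: parameter -> half-width.

    Draws are uniform on [base - hw, base + hw], then clamped to the
    physical domain (voidage into (0, 1), positives stay positive).
    """

    halfwidths: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, hw in self.halfwidths.items():
            if hw < 0:
                raise ValueError(f"half-width for {name!r} must be >= 0")

    def draw(self, base: Mapping[str, float], rng: np.random.Generator) -> dict:
        out = {}
        for name, b in base.items():
            hw = self.halfwidths.get(name, 0.0)
            v = b + rng.uniform(-hw, hw) if hw > 0 else b
            if name == "voidage":
                v = min(max(v, _TINY), 1.0 - _TINY)
            elif b > 0:
                v = max(v, _TINY)
            out[name] = v
        return out


@dataclass(frozen=True)
class SensitivityResult:
    """Sampled parameters, per-replicate scores and their correlations."""

    samples: pd.DataFrame          # one column per parameter + 'r_squared'
    correlations: pd.DataFrame     # rows: parameter; cols: correlation, p_value
    n_failed: int
    method: str = "pearson"

    def dominant_parameter(self) -> str:
        return self.correlations["correlation"].abs().idxmax()


def _sensitivity_config(
    base: SimulationConfig, draw: Mapping[str, float]
) -> SimulationConfig:
    """Rebuild a config from one perturbed parameter draw.

    K_x is recombined from the perturbed film coefficients; the initial
    soak state and velocity are re-derived from the perturbed voidage and
    partition coefficient so the replicate stays mass-consistent.  The bed
    height stays at the base value: it is a directly observable geometric
    quantity, so a voidage measurement error does not move it.
    """
    material = replace(
        base.material,
        D_is=draw["D_is"],
        particle_size=draw["r"],
        mesh_class=None,
    )
    bed = replace(base.bed, voidage=draw["voidage"], bed_height=base.bed_height_m)
    tp = TransportParams(
        k_int=draw["k_int"],
        k_ext=draw["k_ext"],
        K_x=combine_kx(draw["k_int"], draw["k_ext"]),
        D_ax=draw["D_ax"],
        kext_correlation="perturbed",
        dax_correlation="perturbed",
    )
    return make_config(
        material,
        bed,
        tp,
        fluid=base.fluid,
        duration=base.duration,
        n_cells=base.n_cells,
        n_out=base.n_out,
        rtol=base.rtol,
        atol=base.atol,
    )


def sensitivity_analysis(
    base: SimulationConfig,
    spec: PerturbationSpec | None = None,
    reference: ConcentrationCurve | None = None,
    n: int = 10000,
    seed: int | None = 0,
    method: str = "pearson",
) -> SensitivityResult:
    """Monte-Carlo parameter-error study against a reference curve.

    ``reference`` defaults to the base configuration's own simulated
    effluent.  Replicates whose integration fails are dropped and counted;
    more than 1% failures aborts.  Raises if every half-width is zero
    (the correlation is undefined without variance).
    """
    if spec is None:
        spec = PerturbationSpec(SENSITIVITY_HALFWIDTHS)
    if not any(hw > 0 for hw in spec.halfwidths.values()):
        raise ValueError("all half-widths are zero: R^2 has no variance")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if reference is None:
        reference = simulate_percolation(base).effluent_curve("base reference")
    if reference.times[-1] < base.duration - 1e-9:
        raise ValueError(
            "reference curve must cover the simulated time span "
            f"({reference.times[-1]:g} < {base.duration:g} min)"
        )
    base_params = {
        "voidage": base.bed.voidage,
        "r": base.material.particle_size,
        "D_is": base.material.D_is,
        "k_int": base.transport.k_int,
        "k_ext": base.transport.k_ext,
        "D_ax": base.transport.D_ax,
    }
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    n_failed = 0
    for _ in range(n):
        draw = spec.draw(base_params, rng)
        try:
            result = simulate_percolation(_sensitivity_config(base, draw))
            draw["r_squared"] = r_squared(reference, result)
            rows.append(draw)
        except (SimulationError, ValueError):
            n_failed += 1
            if n_failed > max(1, 0.01 * n):
                raise SimulationError(
                    f">1% of replicates failed ({n_failed}/{n}); "
                    "check the base configuration and intervals"
                )
    samples = pd.DataFrame(rows)
    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    records = {}
    for name in base_params:
        if samples[name].nunique() <= 1:
            records[name] = (np.nan, np.nan)
            continue
        c = corr_fn(samples[name], samples["r_squared"])
        records[name] = (float(c.statistic), float(c.pvalue))
    correlations = pd.DataFrame.from_dict(
        records, orient="index", columns=["correlation", "p_value"]
    )
    correlations.index.name = "parameter"
    return SensitivityResult(
        samples=samples, correlations=correlations, n_failed=n_failed, method=method
    )


@dataclass(frozen=True)
class DesignSpaceTargets:
    """Pass criteria, both evaluated at the horizon: endpoint effluent
    concentration below ``endpoint_conc`` (mg/mL) and cumulative yield
    above ``min_yield`` (mg)."""

    endpoint_conc: float = 0.1
    min_yield: float = 1700.0

    def __post_init__(self) -> None:
        if self.endpoint_conc <= 0 or self.min_yield < 0:
            raise ValueError("invalid targets")


@dataclass(frozen=True)
class DesignSpaceResult:
    """Long-format probability map with in-space mask."""

    table: pd.DataFrame            # axis columns + probability + in_space
    axes: Mapping[str, tuple[float, ...]]
    threshold: float
    n_reps: int
    targets: DesignSpaceTargets

    def probability_at(self, **cell) -> float:
        mask = np.ones(len(self.table), dtype=bool)
        for k, v in cell.items():
            mask &= np.isclose(self.table[k], v)
        sub = self.table[mask]
        if len(sub) != 1:
            raise KeyError(f"cell {cell} matches {len(sub)} rows")
        return float(sub["probability"].iloc[0])

    def in_space(self, **cell) -> bool:
        return self.probability_at(**cell) >= self.threshold


#: Fixed bed/equilibrium parameters for prospective design-space runs.
DESIGN_FIXED = {"alpha": 3.81, "voidage": 0.37, "D_is": 1.21}


def _design_cell_probability(
    cell: Mapping[str, float],
    spec: PerturbationSpec,
    targets: DesignSpaceTargets,
    n_reps: int,
    rng: np.random.Generator,
    *,
    fixed: Mapping[str, float],
    deff: float,
    horizon: float,
    n_cells: int,
    column_diameter: float,
    kext_name: str,
    dax_name: str,
) -> float:
    base = dict(cell)
    n_pass = 0
    for _ in range(n_reps):
        draw = spec.draw(base, rng)
        material = MaterialBatch(
            M0=draw["M0"],
            D_is=fixed["D_is"],
            D_eff=deff,
            particle_size=draw["r"],
        )
        bed = BedSpec(
            column_diameter=column_diameter,
            herb_mass=draw["mass"],
            voidage=fixed["voidage"],
            expansion_coefficient=fixed["alpha"],
            flow_rate=draw["flow"],
        )
        # infeasible by mass balance: cannot ever reach the yield target
        if draw["M0"] * draw["mass"] <= targets.min_yield:
            continue
        try:
            config = make_config(
                material,
                bed,
                kext_name=kext_name,
                dax_name=dax_name,
                duration=horizon,
                n_cells=n_cells,
            )
            result = simulate_percolation(config)
        except (SimulationError, ValueError):
            continue
        ok = (
            result.effluent_concentration[-1] < targets.endpoint_conc
            and result.cumulative_yield[-1] > targets.min_yield
        )
        n_pass += ok
    return n_pass / n_reps


def design_space(
    grid_spec: Mapping[str, Sequence[float]],
    spec: PerturbationSpec | None = None,
    targets: DesignSpaceTargets | None = None,
    n_reps: int = 100,
    threshold: float = 0.9,
    seed: int = 0,
    *,
    fixed: Mapping[str, float] | None = None,
    deff: float = 1.089e-8,
    horizon: float = 400.0,
    n_cells: int = 80,
    column_diameter: float = 0.05,
    kext_name: str = "wilson_geankoplis",
    dax_name: str = "koch_brady",
) -> DesignSpaceResult:
    """Probability-of-meeting-specification map over a parameter grid.

    ``grid_spec`` maps any of ``r`` (m), ``flow`` (mL/min), ``mass`` (g)
    and ``M0`` (mg/g) to its grid values; omitted parameters must be given
    as single fixed values.  Each cell runs ``n_reps`` perturbed
    replicates; each cell uses its own deterministic RNG stream derived
    from ``seed`` and the cell index, so the map is independent of
    evaluation order.
    """
    if spec is None:
        spec = PerturbationSpec(DESIGN_HALFWIDTHS)
    if targets is None:
        targets = DesignSpaceTargets()
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    required = {"r", "flow", "mass", "M0"}
    missing = required - set(grid_spec)
    if missing:
        raise ValueError(f"grid_spec must cover {sorted(required)}; missing {sorted(missing)}")
    fixed = dict(DESIGN_FIXED if fixed is None else fixed)

    names = list(grid_spec)
    axes = {k: tuple(float(v) for v in np.atleast_1d(grid_spec[k])) for k in names}
    rows = []
    for idx, combo in enumerate(itertools.product(*(axes[k] for k in names))):
        cell = dict(zip(names, combo))
        rng = np.random.default_rng([seed, idx])
        prob = _design_cell_probability(
            cell,
            spec,
            targets,
            n_reps,
            rng,
            fixed=fixed,
            deff=deff,
            horizon=horizon,
            n_cells=n_cells,
            column_diameter=column_diameter,
            kext_name=kext_name,
            dax_name=dax_name,
        )
        rows.append({**cell, "probability": prob, "in_space": prob >= threshold})
    table = pd.DataFrame(rows)
    return DesignSpaceResult(
        table=table, axes=axes, threshold=threshold, n_reps=n_reps, targets=targets
    )


def predict_yield_window(
    config: SimulationConfig,
    target_yield: tuple[float, float],
    result: PercolationResult | None = None,
) -> tuple[Optional[float], Optional[float]]:
    """Times (min) at which the cumulative yield crosses the target range.

    Returns ``(t_low, t_high)``; an edge is ``None`` ("not reached") when
    the run's final yield stays below that bound.
    """
    lo, hi = target_yield
    if lo <= 0 or hi <= 0 or hi < lo:
        raise ValueError("target range must be positive and ordered (low <= high)")
    if result is None:
        result = simulate_percolation(config)
    y = result.cumulative_yield
    t = result.times

    def crossing(level: float) -> Optional[float]:
        if y[-1] < level:
            return None
        i = int(np.searchsorted(y, level))
        if i == 0:
            return float(t[0])
        if y[i] == y[i - 1]:
            return float(t[i])
        return float(t[i - 1] + (level - y[i - 1]) * (t[i] - t[i - 1]) / (y[i] - y[i - 1]))

    return crossing(lo), crossing(hi)


def predict_endpoint(
    config: SimulationConfig,
    threshold: float = 0.1,
    result: PercolationResult | None = None,
) -> Optional[float]:
    """Predicted stop time: first time the effluent drops below ``threshold``.

    Runs a fresh simulation of ``config`` unless one is supplied; ``None``
    means the threshold is not reached within the simulated duration.
    """
    if result is None:
        result = simulate_percolation(config)
    return endpoint_time(result, threshold)
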