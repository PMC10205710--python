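"""Pairwise screening of external-transfer x dispersion correlations.

Every combination of the five k_ext and five D_ax correlations is
substituted into the column model for each available experiment; the pair
with the highest average coefficient of determination against the
observed effluent curves is selected.  Ties are broken by registry
declaration order, deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .curves import ConcentrationCurve
from .simulate import (
    PercolationResult,
    SimulationConfig,
    SimulationError,
    r_squared,
    simulate_percolation,
)
from .transport import (
    DAX_CORRELATIONS,
    KEXT_CORRELATIONS,
    TransportParams,
    axial_dispersion,
    combine_kx,
    external_mass_transfer,
)
from dataclasses import replace

__all__ = ["ScreeningResult", "screen_correlation_pairs", "select_best_pair"]


@dataclass(frozen=True)
class ScreeningResult:
    """5x5 grid of average R^2, indexed (D_ax rows, k_ext columns)."""

    grid: pd.DataFrame                       # average R^2; NaN where all failed
    per_experiment: np.ndarray               # (n_dax, n_kext, n_exp), NaN = failed
    kext_names: tuple[str, ...]
    dax_names: tuple[str, ...]
    tie: bool = False

    @property
    def best_pair(self) -> tuple[str, str]:
        return select_best_pair(self)


def _with_pair(
    config: SimulationConfig, kext_name: str, dax_name: str
) -> SimulationConfig:
    """Recompute k_ext and D_ax for one correlation pair, keeping k_int."""
    u = config.interstitial_u
    r = config.material.particle_size
    eps = config.bed.voidage
    k_ext = external_mass_transfer(kext_name, config.fluid, u, r, eps)
    d_ax = axial_dispersion(dax_name, config.fluid, u, r, eps)
    tp = TransportParams(
        k_int=config.transport.k_int,
        k_ext=k_ext,
        K_x=combine_kx(config.transport.k_int, k_ext),
        D_ax=d_ax,
        kext_correlation=kext_name,
        dax_correlation=dax_name,
    )
    return replace(config, transport=tp)


def screen_correlation_pairs(
    experiments: Sequence[tuple[SimulationConfig, ConcentrationCurve]],
) -> ScreeningResult:
    """Score all 25 correlation pairs against the observed effluent curves.

    For each pair and experiment the transport coefficients are recomputed
    from that experiment's bed and material, the column is re-simulated and
    scored with R^2; the grid holds the across-experiment averages.
    Simulation failures are recorded as missing values, not raised.
    """
    if not experiments:
        raise ValueError("need at least one experiment to screen")
    kext_names = tuple(KEXT_CORRELATIONS)
    dax_names = tuple(DAX_CORRELATIONS)
    scores = np.full((len(dax_names), len(kext_names), len(experiments)), np.nan)
    for i, dax_name in enumerate(dax_names):
        for j, kext_name in enumerate(kext_names):
            for k, (config, observed) in enumerate(experiments):
                try:
                    result = simulate_percolation(_with_pair(config, kext_name, dax_name))
                    scores[i, j, k] = r_squared(observed, result)
                except (SimulationError, ValueError):
                    continue
    with np.errstate(invalid="ignore"):
        avg = np.nanmean(scores, axis=2)
    grid = pd.DataFrame(avg, index=list(dax_names), columns=list(kext_names))
    grid.index.name = "dax_correlation"
    grid.columns.name = "kext_correlation"
    # flag exact ties at the maximum
    finite = avg[np.isfinite(avg)]
    tie = bool(finite.size > 1 and (finite == np.nanmax(avg)).sum() > 1)
    return ScreeningResult(
        grid=grid,
        per_experiment=scores,
        kext_names=kext_names,
        dax_names=dax_names,
        tie=tie,
    )


def select_best_pair(result: ScreeningResult) -> tuple[str, str]:
    """(k_ext name, D_ax name) attaining the maximum average R^2.

    Ties resolve to the first pair in registry declaration order (D_ax
    rows scanned outer, k_ext columns inner).
    """
    avg = result.grid.to_numpy()
    if not np.isfinite(avg).any():
        raise ValueError("screening grid is entirely missing; nothing to select")
    best = np.nanmax(avg)
    for i, dax_name in enumerate(result.dax_names):
        for j, kext_name in enumerate(result.kext_names):
            if np.isfinite(avg[i, j]) and avg[i, j] == best:
                return kext_name, dax_name
    raise AssertionError("unreachable")  # pragma: no cover
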