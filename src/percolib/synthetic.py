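"""Synthetic data with known ground truth.

The published impregnation and effluent curves exist only as figures, so
recovery and screening tests run on curves generated here: exact model
output plus additive Gaussian noise truncated at zero.  The noise standard
deviation is expressed in concentration units (mg/mL) to keep recovery
tolerances straightforward.
"""

from __future__ import annotations

import numpy as np

from .curves import ConcentrationCurve
from .kinetics import eval_diffusion, eval_first_order, eval_peleg
from .simulate import SimulationConfig, simulate_percolation

__all__ = [
    "gen_impregnation_curve",
    "gen_percolation_experiment",
]


def _add_noise(values: np.ndarray, noise_sd: float, seed) -> np.ndarray:
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return values.copy()
    rng = np.random.default_rng(seed)
    return np.clip(values + rng.normal(0.0, noise_sd, size=values.shape), 0.0, None)


def gen_impregnation_curve(
    model_name: str,
    params: dict,
    t_grid,
    noise_sd: float = 0.0,
    seed=None,
    *,
    n_terms: int = 3,
) -> ConcentrationCurve:
    """Noisy soaking curve from a named kinetic model.

    ``params`` uses the fit parameter names (``C_eq``/``k``, ``k1``/``k2``
    or ``C_eq``/``D_eff_over_r2``).  Reproducible for a fixed ``seed``.
    """
    t = np.asarray(t_grid, dtype=float)
    if model_name == "first_order":
        clean = eval_first_order(t, params["C_eq"], params["k"])
    elif model_name == "peleg":
        clean = eval_peleg(t, params["k1"], params["k2"])
    elif model_name == "diffusion":
        clean = eval_diffusion(t, params["C_eq"], params["D_eff_over_r2"], n_terms)
    else:
        raise ValueError(f"unknown model {model_name!r}")
    noisy = _add_noise(np.atleast_1d(clean), noise_sd, seed)
    return ConcentrationCurve(t, noisy, label=f"synthetic {model_name} (sd={noise_sd})")


def gen_percolation_experiment(
    config: SimulationConfig,
    noise_sd: float = 0.0,
    seed=None,
    *,
    cadence_min: float | None = None,
) -> tuple[SimulationConfig, ConcentrationCurve]:
    """Simulate an effluent curve and corrupt it with truncated noise.

    Returns the generating config paired with the observed curve, i.e. the
    ground truth a screening or sensitivity study should recover.
    ``cadence_min`` resamples the effluent at a fixed interval (default:
    the simulator output grid).
    """
    result = simulate_percolation(config)
    t = result.times
    c = result.effluent_concentration
    if cadence_min is not None:
        if cadence_min <= 0:
            raise ValueError("cadence_min must be > 0")
        t_s = np.arange(0.0, config.duration + 1e-9, cadence_min)
        c = np.interp(t_s, t, c)
        t = t_s
    noisy = _add_noise(c, noise_sd, seed)
    return config, ConcentrationCurve(
        t, noisy, label=f"synthetic effluent (sd={noise_sd})"
    )
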