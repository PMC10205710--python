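"""Time-concentration curves and their CSV serialization.

A :class:`ConcentrationCurve` holds ordered ``(time, concentration)``
samples from either an impregnation (soaking) experiment or a percolation
effluent record.  Times are minutes, concentrations mg/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CURVE_COLUMNS = ("time_min", "conc_mg_per_ml")


class CurveError(ValueError):
    """Raised for malformed curve data."""


@dataclass(frozen=True)
class ConcentrationCurve:
    """Ordered (time, concentration) samples.

    Parameters
    ----------
    times
        Sampling times in minutes, strictly increasing, all >= 0.
    concentrations
        Concentrations in mg/mL, all >= 0 and finite.
    label
        Free-text description of the curve's origin.
    """

    times: np.ndarray
    concentrations: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or c.ndim != 1 or t.size != c.size:
            raise CurveError("times and concentrations must be 1-D and equal length")
        if t.size == 0:
            raise CurveError("curve must contain at least one sample")
        if not (np.isfinite(t).all() and np.isfinite(c).all()):
            raise CurveError("curve contains non-finite values")
        if (t < 0).any():
            raise CurveError("times must be >= 0")
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise CurveError(
                f"times must be strictly increasing (violated at row {bad[0] + 1})"
            )
        if (c < 0).any():
            raise CurveError("concentrations must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)

    def __len__(self) -> int:
        return self.times.size

    def interpolate(self, at_times: np.ndarray) -> np.ndarray:
        """Linear interpolation of the curve onto ``at_times``."""
        return np.interp(np.asarray(at_times, dtype=float), self.times, self.concentrations)


def read_curve(path) -> ConcentrationCurve:
    """Read a curve from a strict two-column CSV.

    The file must be UTF-8 with a header row ``time_min,conc_mg_per_ml``.
    """
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CurveError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise CurveError(f"{path}: missing required column(s) {missing}")
    for col in CURVE_COLUMNS:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            row = int(bad[0]) + 2 if len(bad) else "?"
            raise CurveError(f"{path}: non-numeric value in '{col}' near line {row}")
    t = df[CURVE_COLUMNS[0]].to_numpy(float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise CurveError(
            f"{path}: times must be strictly increasing (line {int(bad[0]) + 3})"
        )
    return ConcentrationCurve(t, df[CURVE_COLUMNS[1]].to_numpy(float), label=str(path))


def write_curve(curve: ConcentrationCurve, path) -> None:
    """Write a curve as CSV (12 significant digits; read/write round-trips)."""
    df = pd.DataFrame({CURVE_COLUMNS[0]: curve.times, CURVE_COLUMNS[1]: curve.concentrations})
    df.to_csv(path, index=False, float_format="%.12g")
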