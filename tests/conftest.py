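"""Shared fixtures: fast simulation configs built from the built-in tables."""

from __future__ import annotations

import numpy as np
import pytest

import percolib as pl
from percolib.transport import TransportParams, combine_kx


@pytest.fixture(scope="session")
def e1_material() -> pl.MaterialBatch:
    return pl.material_from_batch("D4", "10-24")


@pytest.fixture(scope="session")
def e1_bed() -> pl.BedSpec:
    return pl.bed_from_experiment("E1")


@pytest.fixture(scope="session")
def e1_config(e1_material, e1_bed) -> pl.SimulationConfig:
    """E1 run at full resolution (200 cells, 300 min)."""
    return pl.make_config(e1_material, e1_bed, n_cells=200, duration=300.0)


@pytest.fixture(scope="session")
def e1_fast_config(e1_material, e1_bed) -> pl.SimulationConfig:
    """E1 run at Monte-Carlo resolution (80 cells) for speed-sensitive tests."""
    return pl.make_config(e1_material, e1_bed, n_cells=80, duration=300.0, n_out=151)


@pytest.fixture(scope="session")
def table13_transport() -> TransportParams:
    """The tabulated reference-experiment transport estimates."""
    k_int, k_ext, d_ax = 7.64e-5, 2.20e-3, 4.89e-6
    return TransportParams(
        k_int=k_int,
        k_ext=k_ext,
        K_x=combine_kx(k_int, k_ext),
        D_ax=d_ax,
        kext_correlation="tabulated",
        dax_correlation="tabulated",
    )


@pytest.fixture(scope="session")
def e1_result(e1_config) -> pl.PercolationResult:
    return pl.simulate_percolation(e1_config)
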