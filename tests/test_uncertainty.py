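"""Sensitivity analysis, design space and the two model applications."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import percolib as pl
from percolib.uncertainty import (
    DesignSpaceTargets,
    PerturbationSpec,
    design_space,
    predict_endpoint,
    predict_yield_window,
    sensitivity_analysis,
)


@pytest.fixture(scope="module")
def base_config(request):
    """Reference-experiment config at Monte-Carlo resolution."""
    mat = pl.material_from_batch("D4", "10-24", D_is=1.21)
    bed = pl.bed_from_experiment("E1")
    tp = request.getfixturevalue("table13_transport")
    return pl.make_config(mat, bed, tp, n_cells=80, duration=300.0, n_out=151)


class TestSensitivity:
    def test_all_zero_halfwidths_rejected(self, base_config):
        spec = PerturbationSpec({k: 0.0 for k in
                                 ("voidage", "r", "D_is", "k_int", "k_ext", "D_ax")})
        with pytest.raises(ValueError, match="zero"):
            sensitivity_analysis(base_config, spec, n=10)

    def test_frozen_parameter_has_no_correlation(self, base_config):
        """A parameter with zero half-width cannot correlate with R^2."""
        spec = PerturbationSpec(
            {"voidage": 0.05, "r": 0.0, "D_is": 0.10,
             "k_int": 1e-5, "k_ext": 1e-3, "D_ax": 1e-6}
        )
        res = sensitivity_analysis(base_config, spec, n=150, seed=3)
        assert np.isnan(res.correlations.loc["r", "correlation"])
        assert np.isfinite(res.correlations.loc["D_is", "correlation"])

    def test_partition_coefficient_dominates_off_center_reference(self, base_config):
        """Against a curve whose true D_is sits below the assumed base, the
        partition coefficient carries a strong negative correlation."""
        mat_true = replace(base_config.material, D_is=1.10)
        cfg_true = pl.make_config(
            mat_true, base_config.bed, base_config.transport,
            n_cells=80, duration=300.0, n_out=151,
        )
        _, ref = pl.gen_percolation_experiment(cfg_true, noise_sd=0.0)
        spec = PerturbationSpec(
            {"voidage": 0.0, "r": 0.0, "D_is": 0.10,
             "k_int": 0.0, "k_ext": 0.0, "D_ax": 0.0}
        )
        res = sensitivity_analysis(base_config, spec, reference=ref, n=200, seed=11)
        corr = res.correlations.loc["D_is", "correlation"]
        assert corr < -0.5
        assert res.dominant_parameter() == "D_is"

    def test_correlations_in_unit_interval(self, base_config):
        res = sensitivity_analysis(base_config, n=120, seed=5)
        assert res.correlations["correlation"].dropna().between(-1, 1).all()

    def test_seed_reproducibility(self, base_config):
        a = sensitivity_analysis(base_config, n=60, seed=9)
        b = sensitivity_analysis(base_config, n=60, seed=9)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        pd.testing.assert_frame_equal(a.correlations, b.correlations)

    def test_reference_must_cover_duration(self, base_config):
        short = pl.ConcentrationCurve([0.0, 10.0], [1.0, 0.5])
        with pytest.raises(ValueError, match="cover"):
            sensitivity_analysis(base_config, reference=short, n=10)


ONE_CELL = {"r": [1.425e-3], "flow": [2.0], "mass": [50.0], "M0": [37.28]}


class TestDesignSpace:
    def test_zero_disturbance_deterministic_pass(self):
        """A cell whose deterministic run meets both targets scores exactly 1."""
        spec = PerturbationSpec({"r": 0.0, "flow": 0.0, "mass": 0.0, "M0": 0.0})
        res = design_space(ONE_CELL, spec, n_reps=5, seed=0)
        assert res.probability_at(**{k: v[0] for k, v in ONE_CELL.items()}) == 1.0

    def test_unreachable_yield_target_probability_zero(self):
        """Yield targets above the available M0*m are infeasible by mass balance."""
        targets = DesignSpaceTargets(endpoint_conc=0.1, min_yield=10_000.0)
        res = design_space(ONE_CELL, targets=targets, n_reps=5, seed=0)
        assert res.table["probability"].iloc[0] == 0.0

    def test_seeded_reproducibility_and_order_invariance(self):
        grid = {"r": [1.425e-3], "flow": [2.0, 3.0], "mass": [50.0, 60.0], "M0": [37.28]}
        a = design_space(grid, n_reps=8, seed=4)
        b = design_space(grid, n_reps=8, seed=4)
        pd.testing.assert_frame_equal(a.table, b.table)
        # a single-cell run reproduces the same cell's in-grid probability
        single = design_space(
            {"r": [1.425e-3], "flow": [2.0], "mass": [50.0], "M0": [37.28]},
            n_reps=8, seed=4,
        )
        assert single.table["probability"].iloc[0] == a.probability_at(
            r=1.425e-3, flow=2.0, mass=50.0, M0=37.28
        )

    def test_mask_matches_threshold(self):
        res = design_space(ONE_CELL, n_reps=5, seed=2, threshold=0.9)
        row = res.table.iloc[0]
        assert bool(row["in_space"]) == (row["probability"] >= 0.9)

    def test_missing_axis_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            design_space({"r": [1e-3], "flow": [2.0], "mass": [50.0]}, n_reps=2)


class TestModelApplications:
    def test_yield_window_linear_curve(self, e1_result):
        """Constant 5 mg/mL at 2 mL/min gives 10 mg/min of collected solute."""
        times = np.linspace(0.0, 20.0, 21)
        res = replace(
            e1_result,
            times=times,
            effluent_concentration=np.full(21, 5.0),
            cumulative_yield=10.0 * times,
        )
        t_lo, t_hi = predict_yield_window(e1_result.config, (100.0, 120.0), result=res)
        assert t_lo == pytest.approx(10.0)
        assert t_hi == pytest.approx(12.0)

    def test_yield_window_not_reached(self, e1_fast_config):
        total = e1_fast_config.material.M0 * e1_fast_config.bed.herb_mass
        t_lo, t_hi = predict_yield_window(e1_fast_config, (total * 2, total * 3))
        assert t_lo is None and t_hi is None

    def test_yield_window_inverted_range_rejected(self, e1_fast_config):
        with pytest.raises(ValueError):
            predict_yield_window(e1_fast_config, (200.0, 100.0))

    def test_quantitative_extraction_window_is_ordered(self):
        """A validation-style run has a finite, positively ordered window."""
        mat = pl.MaterialBatch(M0=37.28, D_is=1.21, D_eff=1.089e-8, particle_size=1.425e-3)
        bed = pl.BedSpec(
            column_diameter=0.05, herb_mass=50.0, voidage=0.37,
            expansion_coefficient=3.81, flow_rate=2.0,
        )
        cfg = pl.make_config(mat, bed, duration=400.0, n_cells=80)
        t_lo, t_hi = predict_yield_window(cfg, (1700.0, 1730.0))
        assert t_lo is not None and t_hi is not None
        assert 0.0 < t_lo < t_hi

    def test_endpoint_trivial_cases(self, e1_bed):
        mat = pl.MaterialBatch(M0=0.0, D_is=1.21, D_eff=1.089e-8, particle_size=1.425e-3)
        cfg = pl.make_config(mat, e1_bed, duration=60.0, n_cells=50)
        assert predict_endpoint(cfg, 0.1) == 0.0

    def test_faster_flow_and_more_mass_still_ends_earlier(self):
        """The validation pair ordering: 3 mL/min with 60 g finishes before
        2 mL/min with 50 g."""
        def cfg(flow, mass):
            mat = pl.MaterialBatch(
                M0=37.28, D_is=1.21, D_eff=1.089e-8, particle_size=1.425e-3
            )
            bed = pl.BedSpec(
                column_diameter=0.05, herb_mass=mass, voidage=0.37,
                expansion_coefficient=3.81, flow_rate=flow,
            )
            return pl.make_config(mat, bed, duration=600.0, n_cells=80)

        t_v3 = predict_endpoint(cfg(2.0, 50.0), 0.1)
        t_v4 = predict_endpoint(cfg(3.0, 60.0), 0.1)
        assert t_v3 is not None and t_v4 is not None
        assert t_v4 < t_v3
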