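"""Column-model simulator: conservation, oracles, post-processing."""

from dataclasses import replace

import numpy as np
import pytest

import percolib as pl
from percolib.simulate import endpoint_time, r_squared
from percolib.transport import TransportParams
from percolib._units import ML_PER_M3


def plug_flow_config(e1_material, e1_bed) -> pl.SimulationConfig:
    """Transfer switched off, dispersion negligible: pure advection."""
    tp = TransportParams(
        k_int=1e-30, k_ext=1e-30, K_x=5e-31, D_ax=1e-12,
        kext_correlation="off", dax_correlation="off",
    )
    return pl.make_config(
        e1_material, e1_bed, tp, duration=300.0, n_cells=200, n_out=601
    )


class TestSimulatePercolation:
    def test_mass_conservation(self, e1_result):
        """Liquid + solid + net outflow stays within 0.5% of the inventory."""
        assert e1_result.mass_balance_error < 0.005

    def test_initial_inventory_equals_total_content(self, e1_config):
        """The soak-equilibrium closure books exactly M0*m into the column."""
        cfg = e1_config
        v_bed = cfg.bed_volume_ml
        eps = cfg.bed.voidage
        cw0 = cfg.initial_liquid_concentration
        inventory = eps * v_bed * cw0 + (1 - eps) * v_bed * cfg.material.D_is * cw0
        assert inventory == pytest.approx(
            cfg.material.M0 * cfg.bed.herb_mass, rel=1e-9
        )

    def test_zero_content_gives_zero_everything(self, e1_bed):
        mat = pl.MaterialBatch(M0=0.0, D_is=1.21, D_eff=1.089e-8, particle_size=1.425e-3)
        cfg = pl.make_config(mat, e1_bed, duration=60.0, n_cells=50)
        res = pl.simulate_percolation(cfg)
        assert np.all(res.effluent_concentration == 0.0)
        assert res.cumulative_yield[-1] == 0.0

    def test_plug_flow_half_drop_time(self, e1_material, e1_bed):
        """Without transfer/dispersion the initial liquid washes out as a plug.

        The effluent crosses half its initial value at t* = eps V_bed / Q
        within two grid cells' worth of residence time.
        """
        cfg = plug_flow_config(e1_material, e1_bed)
        res = pl.simulate_percolation(cfg)
        c0 = cfg.initial_liquid_concentration
        t_star = cfg.bed.voidage * cfg.bed_volume_ml / cfg.bed.flow_rate
        t_half = endpoint_time(res, 0.5 * c0)
        assert t_half is not None
        cell_time = t_star / cfg.n_cells
        assert abs(t_half - t_star) <= 2 * cell_time

    def test_effluent_monotone_after_plug_time(self, e1_result):
        """With a clean-solvent inlet the effluent only decays once washing out."""
        c = e1_result.effluent_concentration
        t = e1_result.times
        cfg = e1_result.config
        t_star = cfg.bed.voidage * cfg.bed_volume_ml / cfg.bed.flow_rate
        after = c[t >= t_star]
        assert np.all(np.diff(after) <= 1e-9)

    def test_yield_bounded_by_total_content(self, e1_result):
        total = e1_result.config.material.M0 * e1_result.config.bed.herb_mass
        assert e1_result.cumulative_yield[-1] < total
        assert np.all(np.diff(e1_result.cumulative_yield) >= 0)

    def test_grid_convergence(self, e1_material, e1_bed):
        """Halving the cell size changes the effluent curve by < 1% (L2)."""
        fine = pl.simulate_percolation(
            pl.make_config(e1_material, e1_bed, n_cells=200, duration=300.0)
        )
        coarse = pl.simulate_percolation(
            pl.make_config(e1_material, e1_bed, n_cells=100, duration=300.0)
        )
        num = np.linalg.norm(fine.effluent_concentration - coarse.effluent_concentration)
        den = np.linalg.norm(fine.effluent_concentration)
        assert num / den < 0.01

    def test_higher_flow_earlier_endpoint(self, e1_material, e1_bed):
        """Raising the pump flow speeds up washout."""
        endpoints = []
        for q in (2.0, 3.0, 4.0):
            bed = replace(e1_bed, flow_rate=q)
            cfg = pl.make_config(e1_material, bed, duration=600.0, n_cells=80)
            endpoints.append(pl.predict_endpoint(cfg, 0.1))
        assert None not in endpoints
        assert endpoints[0] > endpoints[1] > endpoints[2]

    def test_larger_particles_later_endpoint(self, e1_bed):
        """Coarser grinds extract slower (weaker transfer, more dispersion)."""
        endpoints = []
        for mesh in ("10-24", "5-10"):
            mat = pl.material_from_batch("D4", mesh)
            cfg = pl.make_config(mat, e1_bed, duration=900.0, n_cells=80)
            endpoints.append(pl.predict_endpoint(cfg, 0.1))
        assert None not in endpoints
        assert endpoints[1] > endpoints[0]

    def test_too_few_cells_rejected(self, e1_material, e1_bed):
        with pytest.raises(ValueError):
            pl.make_config(e1_material, e1_bed, n_cells=5)


class TestCumulativeYield:
    def test_constant_effluent(self, e1_result):
        """Trapezoidal yield of a constant 1 mg/mL curve at 2 mL/min."""
        res = replace(
            e1_result,
            times=np.linspace(0, 10, 11),
            effluent_concentration=np.ones(11),
            cumulative_yield=np.zeros(11),
        )
        assert pl.cumulative_yield(res, Q=2.0) == pytest.approx(20.0)

    def test_zero_curve(self, e1_result):
        res = replace(
            e1_result,
            times=np.linspace(0, 10, 11),
            effluent_concentration=np.zeros(11),
        )
        assert pl.cumulative_yield(res, Q=2.0) == 0.0

    def test_long_run_approaches_total_content(self, e1_material, e1_bed):
        """At ~10x the plug time nearly all of M0*m has been collected."""
        cfg = pl.make_config(e1_material, e1_bed, duration=1200.0, n_cells=80)
        res = pl.simulate_percolation(cfg)
        total = e1_material.M0 * e1_bed.herb_mass
        assert res.cumulative_yield[-1] == pytest.approx(total, rel=0.02)


class TestEndpointTime:
    def _result(self, e1_result, times, conc):
        return replace(
            e1_result,
            times=np.asarray(times, float),
            effluent_concentration=np.asarray(conc, float),
        )

    def test_linear_interpolation(self, e1_result):
        res = self._result(e1_result, [10.0, 20.0], [0.12, 0.08])
        assert endpoint_time(res, 0.1) == pytest.approx(15.0)

    def test_never_reached(self, e1_result):
        res = self._result(e1_result, [0.0, 10.0, 20.0], [3.0, 2.0, 1.0])
        assert endpoint_time(res, 0.1) is None

    def test_threshold_above_initial(self, e1_result):
        res = self._result(e1_result, [0.0, 10.0], [0.5, 0.4])
        assert endpoint_time(res, 1.0) == 0.0

    def test_nonpositive_threshold_rejected(self, e1_result):
        with pytest.raises(ValueError):
            endpoint_time(e1_result, 0.0)


class TestRSquared:
    def test_perfect_prediction(self):
        obs = pl.ConcentrationCurve([0, 1, 2], [1.0, 2.0, 3.0])
        assert r_squared(obs, obs) == pytest.approx(1.0)

    def test_mean_prediction_scores_zero(self):
        obs = pl.ConcentrationCurve([0, 1, 2], [1.0, 2.0, 3.0])
        pred = pl.ConcentrationCurve([0, 1, 2], [2.0, 2.0, 2.0])
        assert r_squared(obs, pred) == pytest.approx(0.0)

    def test_half_explained(self):
        obs = pl.ConcentrationCurve([0, 1, 2], [1.0, 2.0, 3.0])
        pred = pl.ConcentrationCurve([0, 1, 2], [1.0, 2.0, 4.0])
        assert r_squared(obs, pred) == pytest.approx(0.5)

    def test_constant_observed_rejected(self):
        obs = pl.ConcentrationCurve([0, 1, 2], [2.0, 2.0, 2.0])
        pred = pl.ConcentrationCurve([0, 1, 2], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            r_squared(obs, pred)

    def test_interpolates_prediction_onto_observed_grid(self):
        obs = pl.ConcentrationCurve([0.5, 1.5], [1.5, 2.5])
        pred = pl.ConcentrationCurve([0, 1, 2], [1.0, 2.0, 3.0])
        assert r_squared(obs, pred) == pytest.approx(1.0)
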