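"""Bioheat solver: conservation, closed-form limits, reference solutions."""

import numpy as np
import pytest

from fusht.acoustics import HeatSourceField
from fusht.bioheat import (
    BHTEConfig,
    PennesSolver,
    TemperatureField,
    equilibrate,
    initial_temperature,
    run_treatment,
    stability_dt,
    step,
)
from fusht.control import HysteresisController
from fusht.grids import SimulationGrid
from fusht.materials import LayeredPhantom, MaterialMap, Medium, build_material_map

from conftest import single_voxel_map
from _oracles import ftcs_1d, relay_duty_cycle

INSULATED = BHTEConfig(boundary="insulated")


def _enthalpy(mats, T):
    return float((mats.density * mats.specific_heat * T).sum()) * mats.grid.voxel_volume


class TestStep:
    def test_uniform_field_is_stationary(self, uniform_tissue):
        T = TemperatureField(uniform_tissue.grid,
                             np.full(uniform_tissue.grid.shape, 37.0))
        out = step(T, None, 0.05, INSULATED, uniform_tissue)
        np.testing.assert_array_equal(out.values, T.values)

    def test_energy_budget_per_step(self, uniform_tissue, rng):
        """Insulated, perfusion-free box: enthalpy changes by exactly
        ΣQ·ΔV·dt each step (discrete conservation to round-off)."""
        g = uniform_tissue.grid
        T = rng.uniform(36.0, 40.0, g.shape)
        q = rng.uniform(0.0, 1e6, g.shape)
        solver = PennesSolver(uniform_tissue, INSULATED)
        dt = solver.dt
        for _ in range(10):
            T2 = solver.step(T, q, dt)
            dh = _enthalpy(uniform_tissue, T2) - _enthalpy(uniform_tissue, T)
            assert dh == pytest.approx(q.sum() * g.voxel_volume * dt, rel=1e-12)
            T = T2

    def test_enthalpy_constant_source_free(self, uniform_tissue, rng):
        g = uniform_tissue.grid
        T = rng.uniform(30.0, 45.0, g.shape)
        h0 = _enthalpy(uniform_tissue, T)
        solver = PennesSolver(uniform_tissue, INSULATED)
        for _ in range(1000):
            T = solver.step(T, None, solver.dt)
        assert _enthalpy(uniform_tissue, T) == pytest.approx(h0, rel=1e-12)

    def test_maximum_principle(self, uniform_tissue, rng):
        g = uniform_tissue.grid
        T = rng.uniform(20.0, 50.0, g.shape)
        lo, hi = T.min(), T.max()
        solver = PennesSolver(uniform_tissue, INSULATED)
        for _ in range(200):
            T = solver.step(T, None, solver.dt)
        assert T.min() >= lo - 1e-9 and T.max() <= hi + 1e-9

    def test_perfusion_strictly_cools_above_arterial(self, tiny_grid, rng):
        medium = Medium("perf", 1060.0, 1560.0, 0.0, 0.5, 3700.0, 2.0)
        mats = MaterialMap.uniform(tiny_grid, medium)
        T = rng.uniform(38.0, 42.0, tiny_grid.shape)  # all above Ta = 37
        solver = PennesSolver(mats, INSULATED)
        h = _enthalpy(mats, T)
        for _ in range(20):
            T = solver.step(T, None, solver.dt)
            h2 = _enthalpy(mats, T)
            assert h2 < h
            h = h2

    def test_unstable_dt_rejected(self, uniform_tissue):
        T = TemperatureField(uniform_tissue.grid,
                             np.full(uniform_tissue.grid.shape, 37.0))
        bound = stability_dt(uniform_tissue)
        with pytest.raises(ValueError, match="stability"):
            step(T, None, 2.1 * bound, INSULATED, uniform_tissue)

    def test_stability_bound_matches_textbook_uniform(self, uniform_tissue):
        """For a uniform 3-D medium the face-wise bound reduces to
        ρCΔx²/(2·d·k)."""
        bound = stability_dt(uniform_tissue)
        expected = 1060.0 * 3700.0 * (1e-3) ** 2 / (2 * 3 * 0.5)
        assert bound == pytest.approx(expected, rel=1e-12)

    def test_two_medium_rod_matches_fine_grid_reference(self):
        """Coarse 1-D two-layer rod vs an independent 4× finer explicit
        solver: max error < 1% of the temperature range after 100 steps."""
        n, dx = 40, 1e-3
        k = np.where(np.arange(n) < n // 2, 0.6, 0.2)
        rc = np.where(np.arange(n) < n // 2, 4.0e6, 3.5e6)
        T0 = np.where(np.arange(n) < n // 2, 45.0, 37.0)

        grid = SimulationGrid((dx, dx, dx), (n, 1, 1))
        mats = MaterialMap(
            grid=grid,
            density=np.ones((n, 1, 1)),
            sound_speed=np.full((n, 1, 1), 1500.0),
            attenuation=np.zeros((n, 1, 1)),
            conductivity=k.reshape(n, 1, 1).astype(float),
            specific_heat=rc.reshape(n, 1, 1).astype(float),  # rho=1 => rhoC
            perfusion=np.zeros((n, 1, 1)),
            medium_id=np.zeros((n, 1, 1), dtype=np.int8),
        )
        solver = PennesSolver(mats, INSULATED)
        dt = solver.dt
        T = T0.reshape(n, 1, 1).astype(float)
        for _ in range(100):
            T = solver.step(T, None, dt)

        refine = 4
        fine_k = np.repeat(k, refine)
        fine_rc = np.repeat(rc, refine)
        fine_T0 = np.repeat(T0, refine).astype(float)
        sub = 16  # fine dt divisor, comfortably stable at dx/4
        ref = ftcs_1d(fine_T0, fine_k, fine_rc, dx / refine, dt / sub, 100 * sub)
        ref_coarse = ref.reshape(n, refine).mean(axis=1)

        err = np.abs(T[:, 0, 0] - ref_coarse).max() / (T0.max() - T0.min())
        assert err < 0.01


class TestEquilibrate:
    def test_uniform_start_stays_at_equilibrium(self, uniform_tissue):
        cfg = BHTEConfig(boundary="insulated", tissue_initial=37.0,
                         water_initial=37.0, equilibration_duration=30.0)
        out = equilibrate(uniform_tissue, cfg)
        np.testing.assert_allclose(out.values, 37.0, atol=1e-9)
        assert out.time == pytest.approx(30.0)

    def test_lumped_perfusion_exponential(self):
        """k→0, uniform start at 30 °C, Ta = 37: the solver reproduces
        T(t) = 37 − 7·exp(−t/τ) with τ = ρC/(w·C_b) to <0.5% at t = τ."""
        grid = SimulationGrid((1e-3,) * 3, (3, 3, 3))
        w, cb, rho, cp = 2.0, 3700.0, 1060.0, 3700.0
        medium = Medium("lump", rho, 1500.0, 0.0, 0.0, cp, w)
        mats = MaterialMap.uniform(grid, medium)
        tau = rho * cp / (w * cb)
        cfg = BHTEConfig(boundary="insulated", dt=tau / 500,
                         tissue_initial=30.0, water_initial=30.0,
                         blood_specific_heat=cb)
        out = equilibrate(mats, cfg, duration=tau)
        expected = 37.0 - 7.0 * np.exp(-1.0)
        assert out.values[1, 1, 1] == pytest.approx(expected, rel=0.005)

    def test_water_near_skin_cooler_than_deep_tissue(self):
        """After equilibration from 37/23 °C the water just above the skin
        stays colder than the perfused deep tissue."""
        grid = SimulationGrid.from_extent(1e-3, 12e-3, 40e-3)
        phantom = LayeredPhantom.default_for_focus(31.5e-3)
        mats = build_material_map(phantom, grid)
        cfg = BHTEConfig(equilibration_duration=120.0)
        out = equilibrate(mats, cfg)
        i, j = grid.axis_index
        k_skin_top = int(np.searchsorted(grid.z, phantom.water_standoff))
        assert out.values[i, j, k_skin_top - 2] < out.values[i, j, -3]

    def test_dirichlet_faces_held(self):
        grid = SimulationGrid.from_extent(1e-3, 8e-3, 40e-3)
        phantom = LayeredPhantom.default_for_focus(31.5e-3)
        mats = build_material_map(phantom, grid)
        cfg = BHTEConfig(equilibration_duration=60.0)
        out = equilibrate(mats, cfg)
        np.testing.assert_allclose(out.values[:, :, 0], 23.0, atol=1e-12)
        np.testing.assert_allclose(out.values[:, :, -1], 37.0, atol=1e-12)


class TestRunTreatment:
    def test_zero_source_never_exceeds_source_free_path(self, uniform_tissue):
        g = uniform_tissue.grid
        T0 = TemperatureField(g, np.full(g.shape, 37.0))
        q = HeatSourceField(grid=g, q=np.zeros(g.shape))
        ctrl = HysteresisController(sensor_index=(3, 3, 4))
        cfg = BHTEConfig(boundary="insulated")
        hist = run_treatment(T0, q, ctrl, 10.0, cfg, uniform_tissue)
        np.testing.assert_allclose(hist.final_field.values, 37.0, atol=1e-9)
        assert hist.times[-1] == pytest.approx(10.0)
        assert np.all(np.diff(hist.times) > 0)

    def test_relay_duty_cycle_matches_analytic_oscillator(self):
        """Single voxel, constant heating while ON, Newtonian (perfusion)
        cooling while OFF: duty cycle matches the closed-form two-rate
        relay oscillation within 2%."""
        w, cb = 2.0, 3700.0
        mats = single_voxel_map(perfusion=w)
        rho_c = 1060.0 * 3700.0
        gamma = w * cb / rho_c
        q_c = 0.3  # degC/s while ON
        q = HeatSourceField(grid=mats.grid,
                            q=np.full((1, 1, 1), q_c * rho_c))
        cfg = BHTEConfig(boundary="insulated", dt=0.005, blood_specific_heat=cb)
        ctrl = HysteresisController(sensor_index=(0, 0, 0))
        T0 = TemperatureField(mats.grid, np.full((1, 1, 1), 41.5))
        hist = run_treatment(T0, q, ctrl, 600.0, cfg, mats)

        t_on, t_off, duty = relay_duty_cycle(q_c, gamma, 37.0, 41.5, 42.0)
        # measure over whole cycles: between first and last OFF->ON switch
        s = hist.source_on.astype(int)
        rises = np.nonzero(np.diff(s) == 1)[0]
        assert len(rises) >= 3
        span = slice(rises[0] + 1, rises[-1] + 1)
        measured = s[span].mean()
        assert measured == pytest.approx(duty, rel=0.02)
        # period as well, not just the ratio
        period = (hist.times[rises[-1]] - hist.times[rises[0]]) / (len(rises) - 1)
        assert period == pytest.approx(t_on + t_off, rel=0.02)

    def test_sensor_required_inside_grid(self, uniform_tissue):
        g = uniform_tissue.grid
        T0 = TemperatureField(g, np.full(g.shape, 37.0))
        q = HeatSourceField(grid=g, q=np.zeros(g.shape))
        cfg = BHTEConfig(boundary="insulated")
        with pytest.raises(ValueError, match="sensor"):
            run_treatment(T0, q, HysteresisController(), 1.0, cfg, uniform_tissue)
        bad = HysteresisController(sensor_index=(99, 0, 0))
        with pytest.raises(ValueError, match="sensor"):
            run_treatment(T0, q, bad, 1.0, cfg, uniform_tissue)

    def test_grid_mismatch_rejected(self, uniform_tissue):
        g = uniform_tissue.grid
        other = SimulationGrid((1e-3,) * 3, (3, 3, 3))
        T0 = TemperatureField(g, np.full(g.shape, 37.0))
        q = HeatSourceField(grid=other, q=np.zeros(other.shape))
        ctrl = HysteresisController(sensor_index=(0, 0, 0))
        with pytest.raises(ValueError, match="grid"):
            run_treatment(T0, q, ctrl, 1.0, BHTEConfig(boundary="insulated"),
                          uniform_tissue)
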