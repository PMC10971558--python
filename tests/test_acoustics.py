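"""Acoustic field: Rayleigh integral vs closed forms, units, scaling."""

import numpy as np
import pytest

from fusht.acoustics import (
    H224,
    PressureAmplitudeField,
    TransducerSpec,
    calibrate_focal_pressure,
    focal_metrics,
    heat_source,
    intensity_from_pressure,
    rayleigh_pressure_field,
)
from fusht.grids import SimulationGrid
from fusht.materials import (
    LayeredPhantom,
    MaterialMap,
    WATER,
    build_material_map,
)

from _oracles import oneil_axial_amplitude

NARROW = SimulationGrid.from_extent(0.4e-3, 4e-3, 50e-3)


@pytest.fixture(scope="module")
def narrow_water_field():
    """Lossless water field on a thin axial column of the default grid."""
    return rayleigh_pressure_field(H224, NARROW)


class TestRayleighField:
    def test_on_axis_matches_closed_form(self, narrow_water_field):
        """On-axis amplitude equals the spherical-cap closed form to <1%
        at every axial sample beyond 5 mm from the apex."""
        z, p = narrow_water_field.on_axis()
        ref = H224.surface_pressure * oneil_axial_amplitude(
            H224.frequency, H224.aperture_diameter, H224.radius_of_curvature, z
        )
        sel = z >= 5e-3
        rel = np.abs(p[sel] - ref[sel]) / np.maximum(ref[sel], 1e-300)
        assert rel.max() < 0.01

    def test_zero_drive_gives_zero_field(self):
        tx = TransducerSpec(350e3, 44e-3, 31.5e-3, surface_pressure=0.0)
        f = rayleigh_pressure_field(tx, NARROW)
        assert np.all(f.amplitude == 0.0)

    def test_linear_in_surface_pressure(self):
        grid = SimulationGrid.from_extent(0.4e-3, 2e-3, 40e-3)
        f1 = rayleigh_pressure_field(H224, grid, n_elements=4000)
        tx3 = TransducerSpec(350e3, 44e-3, 31.5e-3, surface_pressure=3.0)
        f3 = rayleigh_pressure_field(tx3, grid, n_elements=4000)
        np.testing.assert_allclose(f3.amplitude, 3.0 * f1.amplitude, rtol=1e-12)

    def test_quadrature_converged_at_focus(self):
        """Doubling the cap element count moves the focal peak by <0.5%."""
        grid = SimulationGrid((0.4e-3,) * 3, (1, 1, 126))
        p1 = rayleigh_pressure_field(H224, grid, n_elements=20_000).amplitude.max()
        p2 = rayleigh_pressure_field(H224, grid, n_elements=40_000).amplitude.max()
        assert abs(p2 - p1) / p2 < 0.005

    def test_grid_too_coarse_rejected(self):
        coarse = SimulationGrid.from_extent(1.0e-3, 4e-3, 50e-3)  # 4.2 ppw
        with pytest.raises(ValueError, match="points per wavelength"):
            rayleigh_pressure_field(H224, coarse)

    def test_focus_outside_grid_rejected(self):
        short = SimulationGrid.from_extent(0.4e-3, 4e-3, 20e-3)
        with pytest.raises(ValueError, match="focus"):
            rayleigh_pressure_field(H224, short)

    def test_attenuation_monotone_below_skin(self):
        """Beyond the skin surface, attenuated amplitude never exceeds the
        lossless-water amplitude."""
        grid = SimulationGrid.from_extent(0.8e-3, 8e-3, 48e-3)
        tx = TransducerSpec(200e3, 44e-3, 31.5e-3)  # longer wavelength: coarse ok
        phantom = LayeredPhantom.default_for_focus(tx.radius_of_curvature)
        mats = build_material_map(phantom, grid)
        lossless = rayleigh_pressure_field(tx, grid, n_elements=4000)
        lossy = rayleigh_pressure_field(tx, grid, mats, n_elements=4000)
        below = ~mats.water_mask
        assert np.all(lossy.amplitude[below] <= lossless.amplitude[below] + 1e-9)

    def test_calibration_sets_focal_peak(self):
        tx = calibrate_focal_pressure(H224, NARROW, 1e6, n_elements=8000)
        f = rayleigh_pressure_field(tx, NARROW, n_elements=8000)
        assert f.amplitude.max() == pytest.approx(1e6, rel=1e-9)


class TestFocalMetrics:
    def test_gaussian_beam_closed_form(self):
        """Lateral −3 dB span of exp(−r²/2σ²) is 2σ√(ln 2) ≈ 1.665 mm for
        σ = 1 mm (half-intensity ⇒ amplitude 1/√2)."""
        grid = SimulationGrid((0.1e-3,) * 3, (101, 101, 101))
        X, Y, Z = np.meshgrid(grid.x, grid.y, grid.z - 5e-3, indexing="ij")
        sigma = 1e-3
        amp = np.exp(-(X**2 + Y**2) / (2 * sigma**2)) * np.exp(-(Z**2) / (2 * (2 * sigma) ** 2))
        m = focal_metrics(PressureAmplitudeField(grid=grid, amplitude=amp))
        expected = 2 * sigma * np.sqrt(np.log(2))
        assert m.lateral_width_3db == pytest.approx(expected, rel=2e-3)
        assert m.axial_length_3db == pytest.approx(2 * expected, rel=2e-3)

    def test_uniform_field_rejected(self):
        grid = SimulationGrid((1e-3,) * 3, (5, 5, 5))
        f = PressureAmplitudeField(grid=grid, amplitude=np.ones(grid.shape))
        with pytest.raises(ValueError, match="unique"):
            focal_metrics(f)

    def test_bowl_dimensions_match_closed_form(self):
        """The −3 dB extents of the simulated bowl field agree with values
        derived independently from the diffraction integral: axial span of
        the closed-form axial solution, lateral span from a fine-quadrature
        reference evaluation (2.92 mm × 12.10 mm for this geometry)."""
        grid = SimulationGrid.from_extent(0.4e-3, 10e-3, 50e-3)
        m = focal_metrics(rayleigh_pressure_field(H224, grid))
        # frozen oracle values computed from the closed forms
        assert m.lateral_width_3db == pytest.approx(2.921e-3, rel=0.01)
        assert m.axial_length_3db == pytest.approx(12.096e-3, rel=0.01)
        # peak sits slightly proximal to the geometric focus
        assert 28e-3 < m.peak_location[2] < 31.5e-3


class TestIntensityAndHeating:
    @pytest.mark.parametrize(
        "p, expected_w_cm2",
        [(1e6, 33.74), (0.0, 0.0), (0.5e6, 8.43)],
    )
    def test_intensity_values(self, p, expected_w_cm2):
        """Ispta = p²/(2ρc) in water; 1 MPa gives 33.7 W/cm² and the value
        scales quadratically in pressure."""
        i = intensity_from_pressure(p, 1000.0, 1482.0)
        assert i / 1e4 == pytest.approx(expected_w_cm2, abs=0.005)

    def test_intensity_rejects_nonpositive_medium(self):
        with pytest.raises(ValueError):
            intensity_from_pressure(1e6, 0.0, 1482.0)
        with pytest.raises(ValueError):
            intensity_from_pressure(1e6, 1000.0, -1.0)

    def test_heat_source_hand_value(self, tiny_grid):
        """Tumor voxel at 1 MPa: α = 9.32·0.35 Np/m ⇒ Q ≈ 1.97e6 W/m³."""
        from fusht.materials import TUMOR

        mats = MaterialMap.uniform(tiny_grid, TUMOR, medium_id=2)
        amp = np.full(tiny_grid.shape, 1e6)
        f = PressureAmplitudeField(grid=tiny_grid, amplitude=amp)
        q = heat_source(f, mats, 350e3)
        expected = (9.32 * 0.35) * 1e12 / (1060.0 * 1560.0)
        assert q.q[0, 0, 0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.97e6, rel=0.01)

    def test_water_never_heats(self, tiny_grid):
        mats = MaterialMap.uniform(tiny_grid, WATER, medium_id=0)
        f = PressureAmplitudeField(grid=tiny_grid,
                                   amplitude=np.full(tiny_grid.shape, 2e6))
        assert np.all(heat_source(f, mats, 350e3).q == 0.0)

    def test_heating_scales_quadratically(self, uniform_tissue, tiny_grid):
        f1 = PressureAmplitudeField(grid=tiny_grid,
                                    amplitude=np.full(tiny_grid.shape, 1e5))
        f2 = PressureAmplitudeField(grid=tiny_grid,
                                    amplitude=np.full(tiny_grid.shape, 2e5))
        q1 = heat_source(f1, uniform_tissue, 350e3).q
        q2 = heat_source(f2, uniform_tissue, 350e3).q
        np.testing.assert_allclose(q2, 4 * q1, rtol=1e-12)

    def test_q_equals_two_alpha_i(self, uniform_tissue, tiny_grid):
        """Unit consistency: Q = 2·α·I with I = p²/(2ρc), exactly."""
        p = 0.7e6
        f = PressureAmplitudeField(grid=tiny_grid,
                                   amplitude=np.full(tiny_grid.shape, p))
        q = heat_source(f, uniform_tissue, 350e3).q[0, 0, 0]
        alpha = 9.32 * 0.35
        i = intensity_from_pressure(p, 1060.0, 1560.0)
        assert q == pytest.approx(2 * alpha * i, rel=1e-12)


class TestTransducerSpec:
    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            TransducerSpec(350e3, 70e-3, 31.5e-3)  # aperture > 2F
        with pytest.raises(ValueError):
            TransducerSpec(-1.0, 44e-3, 31.5e-3)
        with pytest.raises(ValueError):
            TransducerSpec(350e3, 44e-3, 31.5e-3, surface_pressure=-5.0)
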