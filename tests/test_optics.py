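"""Forward coated-sphere model against independent references."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scattercyte import (
    CoreShellCell,
    DetectorConfig,
    MieCoefficients,
    OpticalConfig,
    coated_sphere_coefficients,
    detector_pattern,
    integrated_intensity,
    lsp_intensity,
    lsp_intensity_batch,
    radial_average,
    scattering_amplitudes,
    size_parameters,
)
from oracles import (
    bhmie_coefficients,
    bhmie_lsp,
    brute_force_coated_lsp,
    rayleigh_coated,
    rayleigh_homogeneous,
)


class TestSizeParameters:
    def test_direct_arithmetic(self):
        cell = CoreShellCell(10.0, 0.5, 1.40, 1.38)
        x, y, m1, m2 = size_parameters(cell, OpticalConfig())
        assert y == pytest.approx(np.pi * 10 * 1.334 / 0.6328, rel=1e-12)
        assert x == pytest.approx(y / 2, rel=1e-12)
        assert m1 == pytest.approx(1.40 / 1.334)
        assert m2 == pytest.approx(1.38 / 1.334)

    def test_full_core_identity(self):
        x, y, *_ = size_parameters(CoreShellCell(8.0, 1.0, 1.40, 1.38), OpticalConfig())
        assert x == y

    def test_index_matched_relative_indices(self):
        *_, m1, m2 = size_parameters(CoreShellCell(8.0, 0.8, 1.334, 1.334), OpticalConfig())
        assert m1 == 1.0 and m2 == 1.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(diameter=-1.0, nc_ratio=0.8, ri_nucleus=1.4, ri_cytoplasm=1.38),
            dict(diameter=10.0, nc_ratio=1.2, ri_nucleus=1.4, ri_cytoplasm=1.38),
            dict(diameter=10.0, nc_ratio=0.8, ri_nucleus=2.5, ri_cytoplasm=1.38),
        ],
    )
    def test_invalid_cells_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CoreShellCell(**kwargs)


class TestCoatedCoefficients:
    def test_index_matched_scatters_nothing(self):
        c = coated_sphere_coefficients(30.0, 60.0, 1.0, 1.0)
        assert np.all(c.a == 0) and np.all(c.b == 0)

    def test_homogeneous_limit_matches_bhmie_oracle(self, rng):
        """m_core == m_shell must reduce to the ordinary Mie sphere."""
        worst = 0.0
        for _ in range(100):
            d = rng.uniform(6, 20)
            nc = rng.uniform(0.70, 0.95)
            m = rng.uniform(1.34, 1.45) / 1.334
            x, y, *_ = size_parameters(CoreShellCell(d, nc, 1.40, 1.40), OpticalConfig())
            mine = coated_sphere_coefficients(x, y, m, m)
            a_ref, b_ref = bhmie_coefficients(y, m)
            n = min(len(a_ref), mine.order_count)
            scale = np.max(np.abs(a_ref[:n])) + np.max(np.abs(b_ref[:n]))
            worst = max(
                worst,
                np.max(np.abs(mine.a[:n] - a_ref[:n])) / scale,
                np.max(np.abs(mine.b[:n] - b_ref[:n])) / scale,
            )
        assert worst < 1e-8

    def test_vanishing_core_limit(self):
        """x_core -> 0 converges to a homogeneous sphere of the shell index."""
        optics = OpticalConfig()
        mine = lsp_intensity(CoreShellCell(12.0, 1e-4, 1.40, 1.38), optics).intensities
        ref = bhmie_lsp(12.0, 1.38, optics.angles)
        assert np.max(np.abs(mine - ref) / ref) < 1e-8

    def test_nonphysical_inputs_rejected(self):
        with pytest.raises(ValueError):
            coated_sphere_coefficients(10.0, 5.0, 1.05, 1.04)  # core bigger than cell
        with pytest.raises(ValueError):
            coated_sphere_coefficients(-1.0, 5.0, 1.05, 1.04)


class TestAmplitudes:
    def test_zero_coefficients_give_zero_amplitudes(self):
        c = MieCoefficients(5, np.zeros(5, complex), np.zeros(5, complex))
        s1, s2 = scattering_amplitudes(c, [2.0, 10.0, 30.0])
        assert np.all(s1 == 0) and np.all(s2 == 0)

    def test_forward_limit_symmetry(self):
        """pi_n(1) = tau_n(1), so S1 and S2 coincide as theta -> 0."""
        cell = CoreShellCell(12.0, 0.85, 1.42, 1.39)
        x, y, m1, m2 = size_parameters(cell, OpticalConfig())
        c = coated_sphere_coefficients(x, y, m1, m2)
        s1, s2 = scattering_amplitudes(c, [1e-6])
        assert s1[0] == pytest.approx(s2[0], rel=1e-9)

    def test_rayleigh_dipole_pattern(self):
        """Small particles: |S1| angle-independent, |S2| ~ |cos theta|."""
        d = 0.15 * 0.6328 / (np.pi * 1.334)  # y ~ 0.15, well inside the dipole regime
        x, y, m1, m2 = size_parameters(CoreShellCell(d, 0.9999, 1.40, 1.40), OpticalConfig())
        c = coated_sphere_coefficients(x, y, m1, m2)
        angles = np.array([5.0, 30.0, 60.0, 85.0])
        s1, s2 = scattering_amplitudes(c, angles)
        assert np.ptp(np.abs(s1)) / np.abs(s1[0]) < 0.01
        ratio = np.abs(s2) / (np.abs(s1) * np.abs(np.cos(np.deg2rad(angles))))
        assert np.all(np.abs(ratio - 1) < 0.01)


class TestLspIntensity:
    def test_index_matched_cell_dark(self):
        lsp = lsp_intensity(CoreShellCell(10.0, 0.8, 1.334, 1.334))
        assert np.all(lsp.intensities == 0)

    def test_against_brute_force_coated_reference(self):
        optics = OpticalConfig()
        mine = lsp_intensity(CoreShellCell(15.0, 0.85, 1.42, 1.39), optics).intensities
        ref = brute_force_coated_lsp(15.0, 0.85, 1.42, 1.39, optics.angles)
        assert np.max(np.abs(mine - ref) / ref) < 1e-6

    def test_uniform_index_reduces_to_homogeneous(self):
        """Equal core/shell indices: the core radius must become irrelevant."""
        a = lsp_intensity(CoreShellCell(13.0, 0.5, 1.40, 1.40)).intensities
        b = lsp_intensity(CoreShellCell(13.0, 1.0, 1.40, 1.40)).intensities
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_rayleigh_closed_form_homogeneous_and_coated(self):
        optics = OpticalConfig()
        lam, nm = 0.6328, 1.334
        d = 0.28 * lam / (np.pi * nm)
        cell = CoreShellCell(d, 0.6, 1.45, 1.38)
        x, y, m1, m2 = size_parameters(cell, optics)
        assert y <= 0.3
        mine = lsp_intensity(cell, optics).intensities
        ref = rayleigh_coated(x, y, m1, m2, optics.angles)
        assert np.max(np.abs(mine - ref) / ref) < 0.01
        hom = lsp_intensity(CoreShellCell(d, 0.999999, 1.42, 1.42), optics).intensities
        href = rayleigh_homogeneous(np.pi * d * nm / lam, 1.42 / nm, optics.angles)
        assert np.max(np.abs(hom - href) / href) < 0.01

    def test_batch_matches_scalar_path(self):
        params = np.array(
            [[15.0, 0.85, 1.42, 1.39], [8.5, 0.72, 1.44, 1.35], [19.9, 0.95, 1.36, 1.43]]
        )
        batch = lsp_intensity_batch(params)
        for row, p in zip(batch, params):
            single = lsp_intensity(CoreShellCell(*p)).intensities
            np.testing.assert_allclose(row, single, rtol=1e-8)

    def test_angular_grid_has_281_points(self):
        optics = OpticalConfig()
        assert optics.angles.size == 281
        assert optics.angles[0] == 2.0
        assert optics.angles[-1] == pytest.approx(30.0)

    def test_window_energy_monotone_in_diameter(self):
        """Scattered power into 2-30 deg grows with cell size at fixed indices."""
        totals = [
            integrated_intensity(lsp_intensity(CoreShellCell(float(d), 0.85, 1.42, 1.39)))
            for d in np.arange(6.0, 20.01, 0.5)
        ]
        assert np.all(np.diff(totals) > 0)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        d=st.floats(3.0, 20.0),
        nc=st.floats(0.3, 1.0),
        ri_n=st.floats(1.35, 1.46),
        ri_c=st.floats(1.33, 1.43),
    )
    def test_lsp_always_finite_nonnegative(self, d, nc, ri_n, ri_c):
        lsp = lsp_intensity(CoreShellCell(d, nc, ri_n, ri_c))
        assert np.all(np.isfinite(lsp.intensities))
        assert np.all(lsp.intensities >= 0)


class TestDetectorPair:
    # fine enough that one 0.1-deg step spans several pixels
    DET = DetectorConfig(pixel_count=4800, pixel_pitch=1.5, propagation_distance=6.0)

    def test_constant_lsp_round_trip(self):
        optics = OpticalConfig()
        lsp = lsp_intensity(CoreShellCell(10, 0.8, 1.42, 1.39), optics)
        const = type(lsp)(angles=lsp.angles, intensities=np.ones_like(lsp.intensities))
        img = detector_pattern(const, self.DET)
        rec = radial_average(img, self.DET, optics)
        interior = (optics.angles >= 2.5) & (optics.angles <= 29.5)
        assert np.allclose(rec.intensities[interior], 1.0)

    def test_zero_lsp_gives_zero_image(self):
        optics = OpticalConfig()
        zero = lsp_intensity(CoreShellCell(10, 0.8, 1.334, 1.334), optics)
        assert np.all(detector_pattern(zero, self.DET) == 0)

    def test_m0_round_trip_within_two_percent(self):
        optics = OpticalConfig()
        lsp = lsp_intensity(CoreShellCell(15.66, 0.85, 1.42, 1.39), optics)
        img = detector_pattern(lsp, self.DET)
        rec = radial_average(img, self.DET, optics)
        mid = (optics.angles >= 3.0) & (optics.angles <= 29.0)
        rel = np.abs(rec.intensities[mid] - lsp.intensities[mid]) / lsp.intensities[mid]
        assert np.max(rel) < 0.02

    def test_range_beyond_detector_rejected(self):
        tiny = DetectorConfig(pixel_count=4, pixel_pitch=1.0, propagation_distance=100.0)
        lsp = lsp_intensity(CoreShellCell(10, 0.8, 1.42, 1.39))
        with pytest.raises(ValueError):
            detector_pattern(lsp, tiny)
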