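"""Lookup-table construction and LSP inversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scattercyte import (
    AxisSpec,
    CoreShellCell,
    DEFAULT_GRID,
    GridSpec,
    LSP,
    OpticalConfig,
    batch_extract_features,
    build_grid,
    build_lookup,
    extract_features_matrix,
    load_lookup,
    lsp_intensity,
    lsp_intensity_batch,
    match_lsp,
    normalize_lsp,
    save_lookup,
)
from scattercyte.lookup import _normalize_matrix, match_batch
from scattercyte.population import LSPSet, NoiseModel, add_noise


def tiny_spec() -> GridSpec:
    return GridSpec(
        diameter=AxisSpec(10.0, 12.0, 2.0),
        nc_ratio=AxisSpec(0.80, 0.85, 0.05),
        ri_nucleus=AxisSpec(1.40, 1.42, 0.02),
        ri_cytoplasm=AxisSpec(1.36, 1.38, 0.02),
    )


class TestBuildGrid:
    def test_toy_grid_order_and_count(self):
        grid = build_grid(tiny_spec())
        assert grid.shape == (16, 4)
        # diameter slowest, cytoplasmic index fastest
        np.testing.assert_allclose(grid[0], [10.0, 0.80, 1.40, 1.36])
        np.testing.assert_allclose(grid[1], [10.0, 0.80, 1.40, 1.38])
        np.testing.assert_allclose(grid[2], [10.0, 0.80, 1.42, 1.36])
        np.testing.assert_allclose(grid[8], [12.0, 0.80, 1.40, 1.36])

    def test_default_grid_row_count(self):
        assert DEFAULT_GRID.shape == (57, 26, 21, 11)
        assert DEFAULT_GRID.row_count == 342_342
        assert DEFAULT_GRID.row_count >= 335_000

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ValueError):
            AxisSpec(1.0, 2.0, 5.0)  # step larger than the range

    def test_row_cap_enforced(self):
        spec = GridSpec(max_rows=100)
        with pytest.raises(ValueError):
            build_grid(spec)


class TestNormalize:
    def test_scale_invariance(self):
        i = np.abs(np.random.default_rng(0).normal(5, 1, 281)) + 1.0
        np.testing.assert_allclose(normalize_lsp(i), normalize_lsp(1000.0 * i), atol=1e-12)

    def test_constant_curve_maps_to_zero(self):
        np.testing.assert_allclose(normalize_lsp(np.full(281, 7.3)), np.zeros(281), atol=1e-12)

    def test_m1_like_curve_finite(self):
        lsp = lsp_intensity(CoreShellCell(11.76, 0.85, 1.42, 1.38))
        v = normalize_lsp(lsp)
        assert v.shape == (281,)
        assert np.all(np.isfinite(v))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_lsp(np.zeros(281))

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(scale=st.floats(1e-6, 1e6), seed=st.integers(0, 1000))
    def test_scale_invariance_property(self, scale, seed):
        i = np.abs(np.random.default_rng(seed).normal(5, 1, 50)) + 0.5
        np.testing.assert_allclose(normalize_lsp(i), normalize_lsp(scale * i), atol=1e-12)


class TestMatch:
    def test_self_match_zero_residual(self, toy_table, toy_grid_spec, default_optics):
        """A table curve fed back through matching returns its own row exactly."""
        raw = lsp_intensity_batch(toy_table.params, default_optics)
        for row in (0, 57, 239):
            m = match_lsp(LSP(default_optics.angles, raw[row]), toy_table)
            assert m.row == row
            assert m.residual == 0.0
            assert m.rank_runner_up_gap > 0

    def test_brute_force_scan_equivalence(self, toy_table, default_optics, rng):
        """The matcher must agree with an exhaustive normalized-MSE scan."""
        cells = np.stack(
            [
                rng.uniform(8.5, 15.5, 50),
                rng.uniform(0.76, 0.89, 50),
                rng.uniform(1.385, 1.435, 50),
                rng.uniform(1.345, 1.395, 50),
            ],
            axis=1,
        )
        raw = lsp_intensity_batch(cells, default_optics)
        noisy = add_noise(raw, NoiseModel(0.05), seed=3)
        q = _normalize_matrix(noisy)
        rows, residuals, _ = match_batch(noisy, toy_table)
        for k in range(50):
            scan = np.mean((toy_table.curves - q[k]) ** 2, axis=1)
            assert rows[k] == int(np.argmin(scan))
            assert residuals[k] == pytest.approx(float(scan.min()), rel=1e-10)
            # best residual is a true minimum over every row
            assert np.all(residuals[k] <= scan + 1e-15)

    def test_match_respects_resampling(self, toy_table):
        fine = OpticalConfig(angle_min=1.5, angle_max=30.5, angle_step=0.05)
        lsp = lsp_intensity(CoreShellCell(12.0, 0.85, 1.42, 1.38), fine)
        m = match_lsp(lsp, toy_table)
        assert m.best.diameter == 12.0

    def test_non_overlapping_range_rejected(self, toy_table):
        narrow = OpticalConfig(angle_min=5.0, angle_max=20.0, angle_step=0.1)
        lsp = lsp_intensity(CoreShellCell(12.0, 0.85, 1.42, 1.38), narrow)
        with pytest.raises(ValueError):
            match_lsp(lsp, toy_table)

    def test_noisy_diameter_recovery_monte_carlo(self, toy_table, default_optics):
        """100 noisy copies of the M0 mean cell: median diameter error within
        one grid step of the coarse table."""
        clean = lsp_intensity(CoreShellCell(15.66, 0.85, 1.42, 1.39), default_optics)
        noisy = add_noise(np.tile(clean.intensities, (100, 1)), NoiseModel(0.05), seed=9)
        feats = extract_features_matrix(noisy, ["M0"] * 100, toy_table)
        med = np.median(np.abs(feats["D_um"] - 15.66))
        assert med <= toy_table.grid.diameter.step


class TestFeatureExtraction:
    def test_table_curves_give_zero_residual_rows(self, toy_table, default_optics):
        raw = lsp_intensity_batch(toy_table.params, default_optics)[:3]
        lsps = [LSP(default_optics.angles, r, meta={"label": f"c{i}"}) for i, r in enumerate(raw)]
        feats = batch_extract_features(lsps, toy_table)
        assert len(feats) == 3
        assert list(feats["label"]) == ["c0", "c1", "c2"]
        assert np.all(feats["residual"] == 0.0)
        assert not feats["flagged"].any()

    def test_synthetic_batch_round_trip(self, toy_table, default_optics):
        rng = np.random.default_rng(4)
        cells = np.stack(
            [
                rng.uniform(9, 15, 20),
                rng.uniform(0.78, 0.88, 20),
                rng.uniform(1.39, 1.43, 20),
                rng.uniform(1.35, 1.39, 20),
            ],
            axis=1,
        )
        noisy = add_noise(lsp_intensity_batch(cells, default_optics), NoiseModel(0.05), seed=1)
        lspset = LSPSet(default_optics.angles, noisy, labels=["M1"] * 20)
        feats = batch_extract_features(lspset, toy_table)
        assert len(feats) == 20
        assert not feats["flagged"].any()
        fast = extract_features_matrix(noisy, ["M1"] * 20, toy_table)
        pd.testing.assert_frame_equal(
            feats.drop(columns="residual"), fast.drop(columns="residual")
        )

    def test_empty_input_rejected(self, toy_table):
        with pytest.raises(ValueError):
            batch_extract_features([], toy_table)


class TestCache:
    def test_round_trip_and_bit_identical_rebuild(self, tmp_path, default_optics):
        spec = tiny_spec()
        t1 = build_lookup(spec, default_optics, cache_path=tmp_path / "lut.h5")
        t2 = load_lookup(tmp_path / "lut.h5")
        np.testing.assert_array_equal(t1.curves, t2.curves)
        np.testing.assert_array_equal(t1.params, t2.params)
        assert t1.config_hash() == t2.config_hash()
        t3 = build_lookup(spec, default_optics)
        np.testing.assert_array_equal(t1.curves, t3.curves)

    def test_stale_cache_rejected(self, tmp_path, default_optics):
        spec = tiny_spec()
        build_lookup(spec, default_optics, cache_path=tmp_path / "lut.h5")
        other = GridSpec(
            diameter=AxisSpec(10.0, 14.0, 2.0),
            nc_ratio=spec.nc_ratio,
            ri_nucleus=spec.ri_nucleus,
            ri_cytoplasm=spec.ri_cytoplasm,
        )
        with pytest.raises(ValueError, match="different configuration"):
            build_lookup(other, default_optics, cache_path=tmp_path / "lut.h5")

    def test_stored_curves_match_forward_model(self, toy_table, default_optics):
        """Reciprocity: recomputing from stored parameters reproduces the
        stored normalized curves bit-identically."""
        recomputed = _normalize_matrix(lsp_intensity_batch(toy_table.params, default_optics))
        np.testing.assert_array_equal(recomputed, toy_table.curves)
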