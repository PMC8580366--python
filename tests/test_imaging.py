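"""Sliding-window geometry, entropy maps, interpolation, overlay, ROI stats."""

import numpy as np
import pytest

from entropimg import imaging, rf
from entropimg.errors import (
    DegenerateImageError,
    GeometryError,
    MaskError,
    ParameterError,
)
from entropimg.imaging import EntropyConfig, ParametricMap, WindowGeometry
from entropimg.phantom import PhantomSpec, simulate_frame


def _frame(samples, **kw):
    defaults = dict(sampling_rate=12e6, center_frequency=3e6, pulse_length_mm=2.3,
                    line_pitch_mm=0.3, frame_id="t")
    defaults.update(kw)
    return rf.RFFrame(samples=samples, **defaults)


class TestWindowGeometry:
    def test_axial_side_from_pulse_length(self, rng):
        # 2.3 mm pulse at 64.17 um/sample -> round(35.84) = 36 samples
        frame = _frame(rng.normal(size=(200, 64)))
        geo = imaging.window_geometry(frame, EntropyConfig())
        assert frame.axial_spacing_mm == pytest.approx(0.0641667, abs=1e-6)
        assert geo.side_axial_samples == 36
        assert geo.side_lateral_lines == 8  # 2.3 mm / 0.3 mm pitch
        assert geo.step_axial == 18 and geo.step_lateral == 4

    def test_wsl_scales_side_before_rounding(self, rng):
        frame = _frame(rng.normal(size=(400, 64)))
        geo2 = imaging.window_geometry(frame, EntropyConfig(wsl_pulse_lengths=2))
        assert geo2.side_axial_samples == round(2 * 2.3 / frame.axial_spacing_mm)

    def test_window_larger_than_frame(self, rng):
        frame = _frame(rng.normal(size=(20, 4)))
        with pytest.raises(GeometryError):
            imaging.window_geometry(frame, EntropyConfig())

    def test_invalid_config_rejected(self):
        with pytest.raises(ParameterError):
            EntropyConfig(overlap_fraction=1.5)
        with pytest.raises(ParameterError):
            EntropyConfig(estimator="fuzzy")


class TestWindowToSeries:
    def test_line_by_line_concatenation(self):
        window = np.array([[1, 2], [3, 4]])  # lines are columns: L1=[1,3], L2=[2,4]
        np.testing.assert_array_equal(imaging.window_to_series(window), [1, 3, 2, 4])

    def test_single_line_unchanged(self):
        col = np.arange(5.0)[:, None]
        np.testing.assert_array_equal(imaging.window_to_series(col), col.ravel())

    def test_length_is_product_of_sides(self, rng):
        w = rng.normal(size=(7, 3))
        assert imaging.window_to_series(w).size == 21


class TestEntropyMap:
    def test_single_window_frame(self, rng):
        frame = _frame(rng.normal(size=(36, 8)))
        pmap = imaging.entropy_map(frame, EntropyConfig())
        assert pmap.values.shape == (1, 1)

    def test_position_count_formula(self, rng):
        frame = _frame(rng.normal(size=(72, 16)))  # 2x side on both axes
        pmap = imaging.entropy_map(frame, EntropyConfig())
        # floor((2s - s)/(s/2)) + 1 = 3 positions per axis
        assert pmap.values.shape == (3, 3)

    @pytest.mark.parametrize("n_ax,n_lat", [(100, 20), (150, 33)])
    def test_grid_dims_general(self, rng, n_ax, n_lat):
        frame = _frame(rng.normal(size=(n_ax, n_lat)))
        pmap = imaging.entropy_map(frame, EntropyConfig())
        g = pmap.geometry
        assert pmap.values.shape == (
            (n_ax - g.side_axial_samples) // g.step_axial + 1,
            (n_lat - g.side_lateral_lines) // g.step_lateral + 1,
        )

    def test_constant_frame_all_missing(self):
        frame = _frame(np.ones((72, 16)))
        pmap = imaging.entropy_map(frame, EntropyConfig())
        assert np.isnan(pmap.values).all()
        assert pmap.missing_fraction == 1.0

    def test_scale_invariance_both_estimators(self, small_phantom_frame):
        for estimator in ("sample", "shannon"):
            cfg = EntropyConfig(estimator=estimator)
            v1 = imaging.entropy_map(small_phantom_frame, cfg).values
            scaled = _frame(small_phantom_frame.samples * 37.0)
            v2 = imaging.entropy_map(scaled, cfg).values
            np.testing.assert_allclose(v1, v2, rtol=1e-9, equal_nan=True)

    def test_window_size_effect_is_bounded_on_stationary_speckle(self):
        """Growing the window from 1 to 3 pulse lengths shifts the ROI-mean
        sample entropy upward (fewer temporally adjacent template pairs in
        longer series) but by a bounded amount on stationary speckle."""
        spec = PhantomSpec(axial_samples=768, num_lines=64)
        frame, _ = simulate_frame(spec, seed=1)
        e1 = np.nanmean(imaging.entropy_map(frame, EntropyConfig(wsl_pulse_lengths=1)).values)
        e3 = np.nanmean(imaging.entropy_map(frame, EntropyConfig(wsl_pulse_lengths=3)).values)
        assert abs(e1 - e3) / e1 < 0.25

    def test_shannon_estimator_bounded(self, small_phantom_frame):
        cfg = EntropyConfig(estimator="shannon", shannon_bins=200)
        vals = imaging.entropy_map(small_phantom_frame, cfg).values
        assert np.nanmax(vals) <= np.log2(200)
        assert np.nanmin(vals) >= 0.0


def _pmap(values, side=4, step=2, source_shape=None):
    values = np.asarray(values, dtype=float)
    geo = WindowGeometry(side, side, step, step)
    ax = np.arange(values.shape[0]) * step
    lat = np.arange(values.shape[1]) * step
    if source_shape is None:
        source_shape = (ax[-1] + side, lat[-1] + side)
    return ParametricMap(values, ax, lat, source_shape, geo)


class TestUpsample:
    def test_constant_map_constant_image(self):
        out = imaging.upsample_map(_pmap(np.full((3, 3), 2.5)))
        np.testing.assert_allclose(out, 2.5)

    def test_linear_ramp_preserved_between_centers(self):
        vals = np.arange(5.0)[:, None] * np.ones((1, 4))
        pmap = _pmap(vals, side=2, step=2)
        out = imaging.upsample_map(pmap)
        centers = pmap.axial_centers
        rows = np.arange(out.shape[0]).astype(float)
        inside = (rows >= centers[0]) & (rows <= centers[-1])
        expected = (rows[inside] - centers[0]) / 2.0
        np.testing.assert_allclose(out[inside, 1], expected, atol=1e-9)

    def test_edges_take_nearest_center_value(self):
        vals = np.arange(4.0)[:, None] * np.ones((1, 3))
        pmap = _pmap(vals, side=4, step=2)
        out = imaging.upsample_map(pmap)
        np.testing.assert_allclose(out[0], vals[0, 0], atol=1e-12)
        np.testing.assert_allclose(out[-1], vals[-1, 0], atol=1e-12)

    def test_missing_cells_filled_from_neighbours(self):
        vals = np.full((3, 3), 1.0)
        vals[1, 1] = np.nan
        out = imaging.upsample_map(_pmap(vals))
        assert np.isfinite(out).all()
        np.testing.assert_allclose(out, 1.0)

    def test_mostly_missing_warns(self):
        vals = np.full((3, 3), np.nan)
        vals[0, 0] = 2.0
        with pytest.warns(UserWarning, match="low-quality"):
            imaging.upsample_map(_pmap(vals))

    def test_all_missing_raises(self):
        with pytest.raises(DegenerateImageError):
            imaging.upsample_map(_pmap(np.full((2, 2), np.nan)))

    def test_output_shape_matches_source(self, small_phantom_frame):
        pmap = imaging.entropy_map(small_phantom_frame, EntropyConfig())
        out = imaging.upsample_map(pmap)
        assert out.shape == (small_phantom_frame.axial_samples,
                             small_phantom_frame.num_lines)


class TestOverlay:
    def _bmode(self, shape=(16, 16)):
        return rf.BModeImage(np.linspace(0, 1, shape[0] * shape[1]).reshape(shape))

    def test_below_range_maps_to_colormap_minimum(self):
        bm = self._bmode()
        img = imaging.overlay(bm, np.full(bm.values.shape, 1.0), (1.7, 3.0))
        corner = img[0, 0]
        assert np.abs(img.reshape(-1, 3) - corner).max() < 1e-12

    def test_at_range_top_maps_to_colormap_maximum(self):
        import matplotlib.pyplot as plt

        bm = self._bmode()
        img = imaging.overlay(bm, np.full(bm.values.shape, 3.0), (1.7, 3.0))
        top = plt.get_cmap("inferno")(1.0)[:3]
        np.testing.assert_allclose(img[3, 5], top, atol=1e-12)

    def test_roi_restricts_coloring(self):
        bm = self._bmode()
        roi = np.zeros(bm.values.shape, dtype=bool)
        roi[:4] = True
        img = imaging.overlay(bm, np.full(bm.values.shape, 2.0), (1.7, 3.0), roi=roi)
        gray = np.repeat(bm.values[..., None], 3, axis=-1)
        np.testing.assert_allclose(img[4:], gray[4:])
        assert not np.allclose(img[:4], gray[:4])

    def test_invalid_range_rejected(self):
        bm = self._bmode()
        with pytest.raises(ParameterError):
            imaging.overlay(bm, bm.values, (3.0, 1.7))


class TestRoiMean:
    def test_uniform_image(self):
        assert imaging.roi_mean(np.full((5, 5), 3.3)) == pytest.approx(3.3)

    def test_half_and_half(self):
        img = np.ones((4, 4))
        img[2:] = 3.0
        assert imaging.roi_mean(img) == pytest.approx(2.0)

    def test_matches_direct_masked_mean(self, rng):
        img = rng.normal(size=(20, 20))
        roi = rng.random((20, 20)) < 0.4
        roi[0, 0] = True
        assert imaging.roi_mean(img, roi) == pytest.approx(img[roi].mean())

    def test_missing_pixels_excluded(self):
        img = np.array([[1.0, np.nan], [3.0, np.nan]])
        assert imaging.roi_mean(img) == pytest.approx(2.0)

    def test_empty_roi_rejected(self):
        with pytest.raises(MaskError):
            imaging.roi_mean(np.ones((3, 3)), np.zeros((3, 3), dtype=bool))

    def test_all_missing_under_mask_rejected(self):
        img = np.full((3, 3), np.nan)
        roi = np.ones((3, 3), dtype=bool)
        with pytest.raises(DegenerateImageError):
            imaging.roi_mean(img, roi)
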