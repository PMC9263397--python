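import numpy as np
import pytest

from gfcpipe import (
    Bold4D,
    MotionTrace,
    bandpass,
    build_nuisance_design,
    compute_fd,
    detrend_linear,
    discard_initial,
    extract_compartment_mean,
    friston24,
    motion_qc,
    nuisance_regress,
)
from gfcpipe.preprocess import PreprocessingError


def make_bold(data, tr=2.0):
    return Bold4D(np.asarray(data, float), np.eye(4), tr)


class TestDiscardInitial:
    def test_drops_requested_volumes_and_keeps_rest(self, rng):
        data = rng.normal(size=(2, 2, 2, 250))
        out = discard_initial(make_bold(data), 10)
        assert out.n_volumes == 240
        np.testing.assert_array_equal(out.data, data[..., 10:])

    def test_zero_is_identity(self, small_bold):
        out = discard_initial(small_bold, 0)
        np.testing.assert_array_equal(out.data, small_bold.data)

    def test_discarding_everything_is_an_error(self, small_bold):
        with pytest.raises(PreprocessingError):
            discard_initial(small_bold, small_bold.n_volumes)


class TestMotionQC:
    def test_zero_motion_passes(self):
        qc = motion_qc(MotionTrace(np.zeros((50, 6))))
        assert qc.passed and qc.offending_frames.size == 0

    def test_large_translation_fails_and_reports_frame(self):
        params = np.zeros((50, 6))
        params[30, 1] = 2.5
        qc = motion_qc(MotionTrace(params))
        assert not qc.passed
        assert 30 in qc.offending_frames
        assert qc.max_translation_mm == pytest.approx(2.5)

    def test_rotation_just_under_two_degrees_passes(self):
        # 0.0349 rad = 1.9996 degrees: the limit is a strict inequality
        params = np.zeros((50, 6))
        params[10, 4] = 0.0349
        assert motion_qc(MotionTrace(params)).passed

    def test_rotation_over_two_degrees_fails(self):
        params = np.zeros((50, 6))
        params[10, 4] = np.radians(2.1)
        assert not motion_qc(MotionTrace(params)).passed

    def test_displacement_is_relative_to_first_frame(self):
        # constant 5 mm offset from origin, but no motion relative to frame 0
        params = np.full((20, 6), 0.0)
        params[:, 0] = 5.0
        assert motion_qc(MotionTrace(params)).passed


class TestFramewiseDisplacement:
    def test_constant_trace_gives_zero(self):
        fd, mean_fd = compute_fd(MotionTrace(np.ones((30, 6))))
        assert np.all(fd == 0) and mean_fd == 0

    def test_analytic_single_step(self):
        params = np.zeros((3, 6))
        params[1, :3] = 0.1
        params[1, 3:] = 0.001
        fd, _ = compute_fd(MotionTrace(params))
        # 3*0.1 mm + 50 mm * 3*0.001 rad = 0.45; the step back contributes equally
        assert fd[0] == 0
        assert fd[1] == pytest.approx(0.45)
        assert fd[2] == pytest.approx(0.45)

    def test_frame_order_matters(self, rng):
        params = rng.normal(size=(20, 6))
        fd1, _ = compute_fd(MotionTrace(params))
        fd2, _ = compute_fd(MotionTrace(params[::-1]))
        assert not np.allclose(fd1, fd2)

    def test_single_frame_is_an_error(self):
        with pytest.raises(PreprocessingError):
            compute_fd(MotionTrace(np.zeros((1, 6))))


class TestDetrend:
    def test_exact_line_goes_to_zero(self):
        t = np.arange(50, dtype=float)
        data = np.broadcast_to(2 + 3 * t, (2, 2, 2, 50)).copy()
        out = detrend_linear(make_bold(data))
        assert np.allclose(out.data, 0, atol=1e-9)

    def test_residuals_orthogonal_to_trend_regressors(self, small_bold):
        out = detrend_linear(small_bold)
        t = np.arange(small_bold.n_volumes, dtype=float)
        series = out.data.reshape(-1, small_bold.n_volumes)
        assert np.abs(series.sum(axis=1)).max() < 1e-8
        assert np.abs(series @ t).max() < 1e-6

    def test_idempotent(self, small_bold):
        once = detrend_linear(small_bold)
        twice = detrend_linear(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-10)


class TestBandpass:
    def make_sine(self, hz, t=240, tr=2.0):
        time = np.arange(t) * tr
        data = np.broadcast_to(np.sin(2 * np.pi * hz * time), (2, 2, 2, t)).copy()
        return make_bold(data, tr)

    def test_in_band_sine_passes_through(self):
        bold = self.make_sine(0.04)
        out = bandpass(bold)
        ratio = out.data[0, 0, 0].std() / bold.data[0, 0, 0].std()
        assert abs(ratio - 1) < 0.05

    def test_out_of_band_sine_is_rejected(self):
        bold = self.make_sine(0.2)
        out = bandpass(bold)
        assert out.data[0, 0, 0].std() < 0.01 * bold.data[0, 0, 0].std()

    def test_ideal_filter_zeroes_out_of_band_bins(self, small_bold):
        out = bandpass(small_bold, 0.01, 0.08)
        spec = np.abs(np.fft.rfft(out.data, axis=-1))
        freqs = np.fft.rfftfreq(small_bold.n_volumes, d=small_bold.tr)
        outside = (freqs < 0.01 - 1e-12) | (freqs > 0.08 + 1e-12)
        assert np.abs(spec[..., outside]).max() < 1e-10

    def test_band_above_nyquist_is_rejected(self, small_bold):
        with pytest.raises(PreprocessingError):
            bandpass(small_bold, 0.01, 0.3)  # Nyquist = 0.25 Hz at TR 2 s

    def test_butterworth_option_attenuates_out_of_band(self):
        # zero-phase IIR filtering leaves edge transients; judge the
        # steady-state response on the interior of the series
        bold = self.make_sine(0.2)
        out = bandpass(bold, filter_type="butterworth")
        interior = slice(50, 190)
        assert (out.data[0, 0, 0, interior].std()
                < 0.05 * bold.data[0, 0, 0, interior].std())


class TestFriston24:
    def test_zero_motion_gives_24_zero_columns(self):
        design = friston24(MotionTrace(np.zeros((40, 6))))
        assert design.columns.shape == (40, 24)
        assert np.all(design.columns == 0)

    def test_lag_and_square_structure(self, rng):
        params = rng.normal(size=(30, 6))
        design = friston24(MotionTrace(params))
        cols = design.columns
        np.testing.assert_array_equal(cols[:, :6], params)
        assert np.all(cols[0, 6:12] == 0)  # lag zero-padded at frame 0
        np.testing.assert_array_equal(cols[1:, 6:12], params[:-1])
        np.testing.assert_allclose(cols[:, 12:18], cols[:, :6] ** 2)
        np.testing.assert_allclose(cols[:, 18:24], cols[:, 6:12] ** 2)


class TestCompartmentMean:
    def test_singleton_mask_returns_that_voxel(self, small_bold):
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 2, 3] = True
        np.testing.assert_array_equal(
            extract_compartment_mean(small_bold, mask), small_bold.data[1, 2, 3]
        )

    def test_mean_of_two_voxels_is_their_average(self, small_bold):
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        expected = (small_bold.data[0, 0, 0] + small_bold.data[1, 1, 1]) / 2
        np.testing.assert_allclose(
            extract_compartment_mean(small_bold, mask), expected
        )

    def test_constant_image_gives_constant_series(self):
        bold = make_bold(np.full((3, 3, 3, 10), 7.0))
        mask = np.ones((3, 3, 3), bool)
        np.testing.assert_allclose(extract_compartment_mean(bold, mask), 7.0)

    def test_empty_mask_is_an_error(self, small_bold):
        with pytest.raises(PreprocessingError):
            extract_compartment_mean(small_bold, np.zeros((4, 4, 4), bool))


class TestNuisanceRegression:
    def test_series_equal_to_regressor_becomes_zero(self, rng):
        t = 40
        motion = MotionTrace(rng.normal(size=(t, 6)))
        design = build_nuisance_design(motion)
        data = np.broadcast_to(design.columns[:, 0], (2, 2, 2, t)).copy()
        out = nuisance_regress(make_bold(data), design)
        assert np.abs(out.data).max() < 1e-8

    def test_residuals_orthogonal_to_every_column(self, rng, small_bold):
        motion = MotionTrace(rng.normal(size=(small_bold.n_volumes, 6)))
        wm = rng.normal(size=small_bold.n_volumes)
        design = build_nuisance_design(motion, wm_series=wm)
        out = nuisance_regress(small_bold, design)
        series = out.data.reshape(-1, small_bold.n_volumes)
        dots = series @ design.columns
        assert np.abs(dots).max() < 1e-8

    def test_intercept_only_demeans(self, small_bold):
        from gfcpipe.preprocess import NuisanceDesign

        design = NuisanceDesign(np.ones((small_bold.n_volumes, 1)), ["intercept"])
        out = nuisance_regress(small_bold, design)
        expected = small_bold.data - small_bold.data.mean(axis=-1, keepdims=True)
        np.testing.assert_allclose(out.data, expected, atol=1e-10)

    def test_collinear_design_error_names_columns(self, rng, small_bold):
        from gfcpipe.preprocess import NuisanceDesign

        base = rng.normal(size=small_bold.n_volumes)
        design = NuisanceDesign(
            np.column_stack([base, 2 * base]), ["wm_mean", "wm_twice"]
        )
        with pytest.raises(PreprocessingError, match="wm_twice"):
            nuisance_regress(small_bold, design)
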