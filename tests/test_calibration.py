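"""Calibration fitting, prediction, inversion and resolution bounds."""

import numpy as np
import pytest

import sheettopo as st
from sheettopo.calibration import build_calibration, stack_frame_offsets

from .conftest import EQ8_COEFFS


class TestBuildCalibration:
    def test_linear_truth_recovered_by_quintic(self):
        z = np.arange(301) * 2.5
        n = 0.29 * z - 0.74
        model = build_calibration(np.column_stack([z, n]), degree=5)
        assert model.coefficients[0] == pytest.approx(-0.74, abs=1e-9)
        assert model.coefficients[1] == pytest.approx(0.29, abs=1e-9)
        np.testing.assert_allclose(model.coefficients[2:], 0.0, atol=1e-12)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)
        assert model.valid_z_range == (0.0, 750.0)

    def test_quintic_truth_recovered_exactly(self):
        z = np.linspace(0, 750, 301)
        poly = np.asarray(EQ8_COEFFS)
        n = np.polynomial.polynomial.polyval(z, poly)
        model = build_calibration(np.column_stack([z, n]), degree=5)
        np.testing.assert_allclose(model.coefficients, poly, rtol=1e-6)

    def test_too_few_points(self):
        z = np.arange(4) * 2.5
        with pytest.raises(ValueError, match="at least"):
            build_calibration(np.column_stack([z, z]), degree=5)

    def test_non_increasing_z_rejected(self):
        z = np.array([0.0, 2.5, 2.5, 5.0, 7.5, 10.0, 12.5, 15.0])
        with pytest.raises(ValueError, match="strictly increasing"):
            build_calibration(np.column_stack([z, z]), degree=1)

    def test_non_monotone_polynomial_flagged(self):
        z = np.linspace(0, 10, 40)
        n = np.sin(z)  # decreasing beyond pi/2
        with pytest.warns(UserWarning, match="not strictly increasing"):
            model = build_calibration(np.column_stack([z, n]), degree=5)
        assert model.monotone_warning
        lo, hi = model.inversion_range
        assert hi < 10.0

    def test_end_to_end_synthetic_stack(self):
        scene = st.preset_scene("flat", seed=12, speckle_contrast=0.15)
        frames = st.render_calibration_stack(scene, n_steps=101, step_um=2.5,
                                             image_shape=(160, 256))
        model = st.calibrate_stack(frames, step_um=2.5, degree=1)
        assert model.linear_slope == pytest.approx(scene.pixels_per_um, rel=0.02)
        assert model.r_squared >= 0.999
        assert model.metadata["n_frames"] == 101

    def test_slope_recovery_across_seeds(self):
        # bias < 1% and spread < 3% over 20 seeded reduced-size runs
        slopes = []
        for seed in range(20):
            scene = st.preset_scene("flat", seed=100 + seed, speckle_contrast=0.15)
            frames = st.render_calibration_stack(scene, n_steps=61, step_um=2.5,
                                                 image_shape=(96, 224))
            model = st.calibrate_stack(frames, step_um=2.5, degree=1)
            slopes.append(model.linear_slope)
        rel = np.asarray(slopes) / 0.29 - 1.0
        assert abs(rel.mean()) < 0.01
        assert rel.std() < 0.03


class TestPredictInvert:
    def test_forward_values(self, eq8_model):
        assert st.predict_offset(eq8_model, 0.0) == pytest.approx(-0.74)
        assert st.predict_offset(eq8_model, 72.0) == pytest.approx(20.20, abs=0.01)
        simple = st.CalibrationModel.from_linear_slope(0.3, 0.0, (0.0, 200.0))
        assert st.predict_offset(simple, 100.0) == pytest.approx(30.0)

    def test_forward_out_of_range(self, eq8_model):
        with pytest.raises(ValueError, match="calibrated range"):
            st.predict_offset(eq8_model, 800.0)

    def test_roundtrip_identity(self, eq8_model):
        for z in np.linspace(10, 750, 100):
            n = st.predict_offset(eq8_model, z)
            assert st.invert_offset(eq8_model, n) == pytest.approx(z, abs=1e-5)

    def test_invert_linear_closed_form(self):
        model = st.CalibrationModel.from_linear_slope(0.29, -0.74, (0.0, 750.0))
        assert st.invert_offset(model, 36.0) == pytest.approx((36 + 0.74) / 0.29, abs=0.01)
        assert st.invert_offset(model, 36.0) == pytest.approx(126.69, abs=0.01)

    def test_invert_printed_polynomial(self, eq8_model):
        assert st.invert_offset(eq8_model, 21.0) == pytest.approx(74.7, abs=0.2)

    def test_invert_out_of_range(self, eq8_model):
        with pytest.raises(ValueError, match="attainable"):
            st.invert_offset(eq8_model, 500.0)
        with pytest.raises(ValueError, match="attainable"):
            st.invert_offset(eq8_model, -5.0)

    def test_high_order_terms_small(self, eq8_model):
        # the fit is dominated by its linear term: the nonlinear part of the
        # printed quintic peaks at ~6% of c1*z (near 530 um) and is below 2%
        # over the 0-200 um range where the instrument's measurements live
        z = np.linspace(10, 750, 500)
        full = np.polynomial.polynomial.polyval(z, eq8_model.coefficients)
        linear = eq8_model.coefficients[0] + eq8_model.linear_slope * z
        ratio = np.abs(full - linear) / np.abs(eq8_model.linear_slope * z)
        assert np.max(ratio) < 0.065
        assert np.max(ratio[z <= 200]) < 0.02


class TestResolutionBound:
    @pytest.mark.parametrize(
        "step, k, expected", [(2.5, 4, 10.0), (2.5, 1, 2.5), (5, 3, 15.0)]
    )
    def test_values(self, step, k, expected):
        assert st.z_resolution_bound(step, k) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            st.z_resolution_bound(0, 4)
        with pytest.raises(ValueError):
            st.z_resolution_bound(2.5, 0)


class TestSerialization:
    def test_json_roundtrip(self, tmp_path, eq8_model):
        path = tmp_path / "model.json"
        eq8_model.save(path)
        loaded = st.CalibrationModel.load(path)
        np.testing.assert_allclose(loaded.coefficients, eq8_model.coefficients)
        assert loaded.valid_z_range == eq8_model.valid_z_range
        assert loaded.r_squared == eq8_model.r_squared

    def test_frame_offsets_reference_is_first_frame(self):
        scene = st.preset_scene("flat", seed=3, speckle_contrast=0.0)
        frames = st.render_calibration_stack(scene, n_steps=5, step_um=10.0,
                                             image_shape=(40, 160))
        ref, offsets = stack_frame_offsets(frames)
        assert offsets[0] == 0.0
        assert ref == pytest.approx(scene.reference_column, abs=0.5)
        assert np.all(np.diff(offsets) >= 0)
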