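"""Point clouds, gridded heightmaps and dimensional measurements."""

import numpy as np
import pytest

import sheettopo as st
from sheettopo.reconstruction import extract_stack_contours

from .conftest import small_field


def _stack(scene, n_frames, step, shape, model, **kwargs):
    frames = st.render_stack(scene, n_frames=n_frames, scan_step_um=step,
                             image_shape=shape)
    return st.ScanStack(frames, step, scene.lateral_scale_um_per_px, model,
                        reference_column=scene.reference_column, **kwargs)


class TestPointCloud:
    def test_flat_scene_is_flat(self, linear_model):
        scene = st.preset_scene("flat", seed=2, speckle_contrast=0.1)
        stack = _stack(scene, 5, 10.0, (60, 160), linear_model)
        pts = st.stack_to_pointcloud(stack)
        assert abs(np.median(pts[:, 2])) < 2.0  # noise floor, um

    def test_coordinate_ranges(self, linear_model):
        scene = st.preset_scene("flat", seed=2, speckle_contrast=0.0)
        stack = _stack(scene, 6, 12.5, (50, 160), linear_model)
        pts = st.stack_to_pointcloud(stack)
        assert pts[:, 0].max() - pts[:, 0].min() == pytest.approx(5 * 12.5)
        assert pts[:, 1].max() - pts[:, 1].min() == pytest.approx(
            49 * scene.lateral_scale_um_per_px
        )

    def test_point_count_equals_valid_rows(self, linear_model):
        scene = st.preset_scene("flat", seed=2, speckle_contrast=0.0)
        stack = _stack(scene, 4, 10.0, (30, 160), linear_model)
        profiles = extract_stack_contours(stack.frames)
        pts = st.stack_to_pointcloud(stack)
        assert pts.shape[0] == sum(int(p.valid.sum()) for p in profiles)

    def test_stair_plateaus_recovered(self, linear_model):
        fh = small_field(120)
        scene = st.preset_scene("stair_10_20", field_height_um=fh, seed=8,
                                speckle_contrast=0.1)
        stack = _stack(scene, 8, 10.0, (120, 192), linear_model)
        pts = st.stack_to_pointcloud(stack)
        b1, b2 = fh / 3, 2 * fh / 3
        lo = np.median(pts[(pts[:, 1] > 30) & (pts[:, 1] < b1 - 30), 2])
        mid = np.median(pts[(pts[:, 1] > b1 + 30) & (pts[:, 1] < b2 - 30), 2])
        hi = np.median(pts[(pts[:, 1] > b2 + 30) & (pts[:, 1] < fh - 30), 2])
        assert lo == pytest.approx(0.0, abs=2.0)
        assert mid == pytest.approx(10.0, abs=2.0)
        assert hi == pytest.approx(30.0, abs=2.0)


class TestGridSurface:
    def test_exact_on_grid_points(self):
        xs, ys = np.meshgrid(np.arange(5.0), np.arange(4.0))
        z = 2 * xs + 3 * ys
        pts = np.column_stack([xs.ravel(), ys.ravel(), z.ravel()])
        hm = st.grid_surface(pts, 1.0, 1.0)
        assert hm.mask.all()
        np.testing.assert_allclose(hm.z, z, atol=1e-9)

    def test_exact_on_planes(self):
        rng = np.random.default_rng(4)
        xy = rng.uniform(0, 100, size=(200, 2))
        z = 0.3 * xy[:, 0] - 0.7 * xy[:, 1] + 5.0
        hm = st.grid_surface(np.column_stack([xy, z]), 5.0, 5.0)
        gx, gy = np.meshgrid(hm.x, hm.y)
        expected = 0.3 * gx - 0.7 * gy + 5.0
        np.testing.assert_allclose(hm.z[hm.mask], expected[hm.mask], atol=1e-9)

    def test_outside_hull_masked(self):
        # points on a diagonal band: grid corners fall outside the hull
        t = np.linspace(0, 1, 50)
        pts = np.column_stack([100 * t, 100 * t + 10 * np.sin(20 * t), t])
        hm = st.grid_surface(pts, 2.0, 2.0)
        assert not hm.mask.all()
        assert np.isnan(hm.z[~hm.mask]).all()

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), np.arange(10.0), np.ones(10)])
        with pytest.raises(ValueError, match="collinear"):
            st.grid_surface(pts, 1.0, 1.0)


class TestStepHeight:
    @pytest.fixture()
    def ramp_surface(self):
        x = np.arange(0, 100.0, 5)
        y = np.arange(0, 80.0, 5)
        z = np.where(np.meshgrid(x, y)[1] > 40, 20.0, 0.0)
        return st.HeightMap(z=z, x=x, y=y, mask=np.ones_like(z, bool))

    def test_identical_regions_zero(self, ramp_surface):
        region = (0, 100, 0, 30)
        assert st.measure_step_height(ramp_surface, region, region) == 0.0

    def test_step_and_antisymmetry(self, ramp_surface):
        hi, lo = (0, 100, 50, 80), (0, 100, 0, 35)
        up = st.measure_step_height(ramp_surface, hi, lo)
        down = st.measure_step_height(ramp_surface, lo, hi)
        assert up == pytest.approx(20.0)
        assert down == -up

    def test_insufficient_cells(self, ramp_surface):
        with pytest.raises(ValueError, match="valid cells"):
            st.measure_step_height(ramp_surface, (0, 1, 0, 1), (0, 100, 0, 30))

    def test_synthetic_stair_within_tolerance(self, linear_model):
        fh = small_field(150)
        scene = st.preset_scene("stair_10_20", field_height_um=fh, seed=21,
                                speckle_contrast=0.15)
        stack = _stack(scene, 40, 10.0, (150, 192), linear_model)
        pts = st.stack_to_pointcloud(stack)
        hm = st.grid_surface(pts, 10.0, scene.lateral_scale_um_per_px)
        b1, b2 = fh / 3, 2 * fh / 3
        h1 = st.measure_step_height(hm, (20, 370, b1 + 50, b2 - 50),
                                    (20, 370, 30, b1 - 50))
        h2 = st.measure_step_height(hm, (20, 370, b2 + 50, fh - 30),
                                    (20, 370, b1 + 50, b2 - 50))
        assert st.relative_error(h1, 10.0) < 8.0
        assert st.relative_error(h2, 20.0) < 8.0


class TestGrooveDepth:
    def test_constant_offsets(self, eq8_model):
        profiles = [
            st.ContourProfile(np.full(40, 99.0), np.ones(40, bool), frame_index=k)
            for k in range(5)
        ]
        depth, offset = st.measure_groove_depth(profiles, 120.0, eq8_model, (0, 40))
        assert offset == -21.0
        assert depth == pytest.approx(74.7, abs=0.2)

    def test_offsets_average_before_rounding(self, eq8_model):
        cols = [100.0, 99.0, 98.0]  # offsets -20, -21, -22 -> mean -21
        profiles = [
            st.ContourProfile(np.full(40, c), np.ones(40, bool), frame_index=k)
            for k, c in enumerate(cols)
        ]
        depth, offset = st.measure_groove_depth(profiles, 120.0, eq8_model, (0, 40))
        assert offset == -21.0
        assert depth == pytest.approx(74.7, abs=0.2)

    def test_no_indenture_raises(self, eq8_model):
        profiles = [st.ContourProfile(np.full(10, np.nan), np.zeros(10, bool))]
        with pytest.raises(ValueError, match="indenture"):
            st.measure_groove_depth(profiles, 120.0, eq8_model, (0, 10))

    def test_synthetic_groove_recovered(self, linear_model):
        fh = small_field(200)
        scene = st.preset_scene("grooves_70", field_height_um=fh, seed=17,
                                speckle_contrast=0.15)
        frames = st.render_stack(scene, n_frames=40, scan_step_um=50.0,
                                 image_shape=(200, 192))
        profiles = extract_stack_contours(frames)
        ls = scene.lateral_scale_um_per_px
        i0 = int((0.5 * fh - 150) / ls)
        i1 = int((0.5 * fh + 150) / ls)
        depth, _ = st.measure_groove_depth(profiles, scene.reference_column,
                                           linear_model, (i0, i1))
        assert st.relative_error(depth, 70.0) < 5.0


class TestRelativeError:
    @pytest.mark.parametrize(
        "measured, reference, expected",
        [(20.25, 20.0, 1.25), (10.80, 10.0, 8.00), (72.0, 74.5, 3.4), (71.0, 74.5, 4.7)],
    )
    def test_published_examples(self, measured, reference, expected):
        assert round(st.relative_error(measured, reference), 2) == pytest.approx(
            expected, abs=0.051
        )

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            st.relative_error(1.0, 0.0)
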