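"""Camera model, registration and thin-lens arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mangosize.camera import (
    KINECT_RGB,
    CameraIntrinsics,
    Extrinsics,
    RGBDFrame,
    crop_rgb_to_depth_fov,
    distort_points,
    mm_to_pixels,
    pixels_to_mm,
    register_depth_to_rgb,
    size_error_from_depth_error,
    undistort_points,
)


def small_intr(cols=64, rows=48, pitch=10.0, fx=3.6, fy=3.9, k1=0.0, k2=0.0):
    return CameraIntrinsics(
        (cols, rows), pitch, fx, fy, (cols / 2.0, rows / 2.0), k1, k2
    )


class TestUndistort:
    def test_zero_coefficients_identity(self, rng):
        intr = small_intr()
        pts = rng.uniform([0, 0], [63, 47], size=(50, 2))
        np.testing.assert_allclose(undistort_points(pts, intr), pts)

    def test_principal_point_fixed(self):
        intr = small_intr(k1=0.05, k2=-0.01)
        p = np.array(intr.principal_point)
        np.testing.assert_allclose(undistort_points(p, intr), p)

    def test_radial_polynomial_matches_scalar_oracle(self):
        # factory RGB coefficients, point at normalised radius 0.5
        intr = KINECT_RGB
        k1, k2 = intr.radial_k1, intr.radial_k2
        cx, cy = intr.principal_point
        px = cx + 0.5 * intr.fx_px  # xn = 0.5, yn = 0
        r2 = 0.25
        scale = 1.0 + k1 * r2 + k2 * r2 * r2  # independent scalar evaluation
        expected_x = cx + 0.5 * scale * intr.fx_px
        out = undistort_points(np.array([px, cy]), intr)
        assert abs(out[0] - expected_x) <= 1e-9
        assert abs(out[1] - cy) <= 1e-9

    def test_invertible_within_working_field(self, rng):
        intr = KINECT_RGB
        pts = rng.uniform([100, 100], [1800, 1000], size=(30, 2))
        back = distort_points(undistort_points(pts, intr), intr)
        np.testing.assert_allclose(back, pts, atol=1e-8)


class TestRegistration:
    def test_identity_geometry_is_identity(self):
        intr = small_intr()
        depth = np.zeros((48, 64), np.int32)
        depth[10:40, 10:50] = 2000
        frame = RGBDFrame(rgb=np.zeros((48, 64, 3), np.uint8), depth=depth)
        out = register_depth_to_rgb(frame, intr, intr, Extrinsics.identity())
        assert out.registered
        np.testing.assert_array_equal(out.depth, depth)

    def test_pure_x_translation_shifts_constant_plane(self):
        # closed form: columns shift by focal_x * t / (D * pitch)
        intr = small_intr()
        D, t = 2000, 100.0
        depth = np.full((48, 64), D, np.int32)
        frame = RGBDFrame(rgb=np.zeros((48, 64, 3), np.uint8), depth=depth)
        ext = Extrinsics(np.eye(3), np.array([t, 0.0, 0.0]))
        out = register_depth_to_rgb(frame, intr, intr, ext)
        shift = int(round(intr.fx_px * t / D))
        expected = np.zeros_like(depth)
        expected[:, shift:] = D
        np.testing.assert_array_equal(out.depth, expected)

    def test_invalid_depth_contributes_nothing(self):
        intr = small_intr()
        depth = np.zeros((48, 64), np.int32)
        depth[5, 5] = 0
        depth[20, 20] = 1500
        frame = RGBDFrame(rgb=np.zeros((48, 64, 3), np.uint8), depth=depth)
        out = register_depth_to_rgb(frame, intr, intr, Extrinsics.identity())
        assert out.depth[5, 5] == 0
        assert out.depth[20, 20] == 1500
        assert np.count_nonzero(out.depth) == 1

    def test_all_invalid_flags_empty_registration(self):
        intr = small_intr()
        frame = RGBDFrame(
            rgb=np.zeros((48, 64, 3), np.uint8), depth=np.zeros((48, 64), np.int32)
        )
        out = register_depth_to_rgb(frame, intr, intr, Extrinsics.identity())
        assert out.meta.get("registration_empty")
        assert not out.depth.any()

    def test_collision_keeps_nearer_surface(self):
        # two depth pixels projecting onto one RGB pixel: smaller depth wins
        intr_d = small_intr(cols=64, rows=48)
        intr_rgb = small_intr(cols=32, rows=24, pitch=20.0)  # half resolution
        depth = np.zeros((48, 64), np.int32)
        depth[24, 32] = 2000
        depth[24, 33] = 1500  # lands on the same coarse RGB pixel
        frame = RGBDFrame(rgb=np.zeros((24, 32, 3), np.uint8), depth=depth)
        out = register_depth_to_rgb(frame, intr_d, intr_rgb, Extrinsics.identity())
        vals = out.depth[out.depth > 0]
        assert 1500 in vals and 2000 not in vals


class TestCrop:
    def test_identical_cameras_full_image(self):
        intr = small_intr()
        img = np.zeros((48, 64, 3), np.uint8)
        crop, rect = crop_rgb_to_depth_fov(img, intr, intr)
        assert rect == (0, 0, 64, 48)
        assert crop.shape == img.shape

    def test_wider_rgb_field_trims_columns(self):
        # RGB has twice the columns at the same focal: horizontal FOV wider,
        # ray-cast oracle says only the central half overlaps the depth FOV
        rgb_intr = small_intr(cols=128, rows=48)
        dep_intr = small_intr(cols=64, rows=48)
        img = np.zeros((48, 128, 3), np.uint8)
        crop, (x0, y0, x1, y1) = crop_rgb_to_depth_fov(img, rgb_intr, dep_intr)
        # oracle: RGB column c sees angle tan = (c - 64)*pitch/f, depth FOV
        # spans +-32*pitch/f
        cols_in = [
            c for c in range(128) if abs(c + 0.5 - 64) <= 32
        ]
        assert x0 == pytest.approx(cols_in[0], abs=1)
        assert x1 == pytest.approx(cols_in[-1] + 1, abs=1)
        assert (y0, y1) == (0, 48)

    def test_crop_always_axis_aligned_within_bounds(self):
        rgb_intr = small_intr(cols=100, rows=60)
        dep_intr = small_intr(cols=64, rows=48)
        img = np.zeros((60, 100, 3), np.uint8)
        _, (x0, y0, x1, y1) = crop_rgb_to_depth_fov(img, rgb_intr, dep_intr)
        assert 0 <= x0 < x1 <= 100
        assert 0 <= y0 < y1 <= 60


class TestThinLens:
    def test_one_pixel_at_two_metres(self):
        # the classic sensitivity number for this sensor: ~1.76 mm per pixel
        assert pixels_to_mm(1, 2000, 3.5157, 3.1) == pytest.approx(1.76, abs=0.01)

    def test_zero_pixels(self):
        assert pixels_to_mm(0, 2000, 3.5157, 3.1) == 0.0

    def test_stalk_filter_width_at_two_metres(self):
        # 8 px at 2 m is roughly 14 mm
        assert pixels_to_mm(8, 2000, 3.5157, 3.1) == pytest.approx(14.0, abs=0.2)

    def test_invalid_distance_raises(self):
        with pytest.raises(ValueError):
            pixels_to_mm(1, 0, 3.5, 3.1)
        with pytest.raises(ValueError):
            pixels_to_mm(1, -5, 3.5, 3.1)

    @given(
        n=st.integers(0, 500),
        D=st.floats(500, 4500),
        f=st.floats(2.0, 30.0),
        p=st.floats(1.0, 12.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_round_trip_and_linearity(self, n, D, f, p):
        size = pixels_to_mm(n, D, f, p)
        assert mm_to_pixels(size, D, f, p) == pytest.approx(n, rel=1e-12, abs=1e-9)
        assert pixels_to_mm(2 * n, D, f, p) == pytest.approx(2 * size, rel=1e-12)
        assert pixels_to_mm(n, 2 * D, f, p) == pytest.approx(2 * size, rel=1e-12)


class TestDepthErrorPropagation:
    def test_ten_mm_error_at_two_metres(self):
        assert size_error_from_depth_error(100, 2000, 10) == pytest.approx(0.5)

    def test_stereo_error_magnitude(self):
        assert size_error_from_depth_error(100, 2000, 155.6) == pytest.approx(
            7.8, abs=0.05
        )

    def test_zero_error(self):
        assert size_error_from_depth_error(100, 2000, 0) == 0.0

    def test_first_order_agreement_with_thin_lens(self):
        # exact thin-lens difference at D vs D+e approaches L*e/D as e -> 0
        L_px, D, f, p = 57, 2000.0, 3.5157, 3.1
        L = pixels_to_mm(L_px, D, f, p)
        for e in (1.0, 5.0, 10.0):
            exact = pixels_to_mm(L_px, D + e, f, p) - L
            approx = size_error_from_depth_error(L, D, e)
            assert abs(exact - approx) / L <= (e / D) ** 2 + 1e-12
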