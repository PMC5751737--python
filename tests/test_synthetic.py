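"""Scene generator ground truth and evaluation metrics."""

import numpy as np
import pytest

from mangosize.detection import BoundingBox
from mangosize.segmentation import SegmentationConfig, to_cielab
from mangosize.sizing import FruitMeasurement
from mangosize.synthetic import (
    FruitSpec,
    FruitTruth,
    SceneParams,
    SceneSpec,
    default_scene_intrinsics,
    evaluate_measurements,
    precision,
    render_scene,
    sample_scene,
)


class TestSampleScene:
    def test_deterministic_given_seed(self):
        params = SceneParams(n_fruit=4)
        assert sample_scene(params, 11) == sample_scene(params, 11)
        assert sample_scene(params, 11) != sample_scene(params, 12)

    def test_empty_scene(self):
        spec = sample_scene(SceneParams(n_fruit=0), 1)
        assert spec.fruits == ()

    def test_ranges(self):
        params = SceneParams(n_fruit=2)
        lengths, widths, dists = [], [], []
        for seed in range(500):
            for fr in sample_scene(params, seed).fruits:
                lengths.append(fr.length_mm)
                widths.append(fr.width_mm)
                dists.append(fr.center_mm[2])
        assert min(lengths) >= 60 and max(lengths) <= 160
        assert min(widths) >= 50 and max(widths) <= 130
        assert min(dists) >= 1000 and max(dists) <= 3000

    def test_impossible_range_errors(self):
        with pytest.raises(ValueError):
            sample_scene(SceneParams(distance_range_mm=(3000, 1000)), 0)


class TestRenderScene:
    def test_bbox_height_matches_thin_lens_inverse(self, scene_intrinsics):
        spec = SceneSpec(
            fruits=(FruitSpec((0, 0, 2000.0), 100.5, 80.0),),
            depth_noise_sigma=0.0, seed=3,
        )
        _, truths = render_scene(spec, scene_intrinsics)
        assert truths[0].bbox.height == pytest.approx(57, abs=1)

    def test_noiseless_depth_is_exact(self, scene_intrinsics):
        spec = SceneSpec(
            fruits=(FruitSpec((0, 0, 1777.0), 100.0, 80.0, stalk_length_px=0),),
            depth_noise_sigma=0.0, leaf_density=0.0, seed=3,
        )
        frame, _ = render_scene(spec, scene_intrinsics)
        vals = np.unique(frame.depth[frame.depth > 0])
        assert list(vals) == [1777]

    def test_occluded_flag(self, scene_intrinsics):
        spec = SceneSpec(
            fruits=(FruitSpec((0, 0, 2000.0), 110.0, 90.0, occlusion_fraction=0.3),),
            depth_noise_sigma=0.0, seed=3,
        )
        _, truths = render_scene(spec, scene_intrinsics)
        assert truths[0].un_occluded is False

    def test_out_of_frame_fruit_dropped(self, scene_intrinsics):
        spec = SceneSpec(
            fruits=(FruitSpec((900.0, 0, 1000.0), 100.0, 80.0),),
            depth_noise_sigma=0.0, seed=3,
        )
        _, truths = render_scene(spec, scene_intrinsics)
        assert truths == []

    def test_fruit_chroma_inside_gate_leaves_outside(self, scene_intrinsics):
        # segmentation solvability: after the Lab->sRGB->Lab round trip the
        # fruit pixels satisfy the chroma gate and leaf pixels violate it
        cfg = SegmentationConfig()
        spec = SceneSpec(
            fruits=(FruitSpec((0, 0, 1800.0), 120.0, 95.0, stalk_length_px=0),),
            depth_noise_sigma=0.0, leaf_density=1e-3, seed=5,
        )
        frame, truths = render_scene(spec, scene_intrinsics)
        lab = to_cielab(frame.rgb)
        fruit = frame.depth == 1800
        a, b = lab[..., 1], lab[..., 2]
        in_gate = (
            (a >= cfg.a_range[0]) & (a <= cfg.a_range[1])
            & (b >= cfg.b_range[0]) & (b <= cfg.b_range[1])
        )
        assert in_gate[fruit].mean() > 0.99
        leaves = (lab[..., 0] > 20) & ~fruit  # bright-ish clutter
        assert leaves.sum() > 500
        assert in_gate[leaves].mean() < 0.05

    def test_dropout_produces_invalid_depth(self, scene_intrinsics):
        spec = SceneSpec(
            fruits=(FruitSpec((0, 0, 1800.0), 120.0, 95.0),),
            depth_noise_sigma=0.0, dropout_fraction=0.5, leaf_density=1e-3, seed=5,
        )
        frame, _ = render_scene(spec, scene_intrinsics)
        spec0 = SceneSpec(
            fruits=spec.fruits, depth_noise_sigma=0.0, leaf_density=1e-3, seed=5
        )
        frame0, _ = render_scene(spec0, scene_intrinsics)
        n0, n1 = (frame0.depth > 0).sum(), (frame.depth > 0).sum()
        assert n1 == pytest.approx(0.5 * n0, rel=0.1)


def _pairs_to_objects(pairs):
    meas, truth = [], []
    for i, (est, ref) in enumerate(pairs):
        bbox = BoundingBox(100 * i, 0, 100 * i + 50, 60)
        meas.append(
            FruitMeasurement("f", bbox, 2000.0, length_mm=est, width_mm=est)
        )
        truth.append(FruitTruth(i, bbox, ref, ref, 2000.0, True))
    return meas, truth


class TestEvaluate:
    def test_identical_measurements(self):
        meas, truth = _pairs_to_objects([(100, 100), (90, 90), (110, 110)])
        rep = evaluate_measurements(meas, truth)
        assert rep.rmse == 0 and rep.bias == 0
        assert rep.r2 == pytest.approx(1.0)
        assert rep.precision == 1.0

    def test_constant_offset(self):
        meas, truth = _pairs_to_objects([(105, 100), (95, 90), (115, 110)])
        rep = evaluate_measurements(meas, truth)
        assert rep.bias == pytest.approx(5.0)
        assert rep.rmse_bc == pytest.approx(0.0, abs=1e-9)

    def test_four_point_hand_computed_case(self):
        pairs = [(100, 103), (90, 88), (110, 111), (95, 99)]
        meas, truth = _pairs_to_objects(pairs)
        rep = evaluate_measurements(meas, truth)
        est = np.array([p[0] for p in pairs], float)
        ref = np.array([p[1] for p in pairs], float)
        res = est - ref
        bias = res.mean()
        rmse = np.sqrt((res**2).mean())
        rmse_bc = np.sqrt(((res - bias) ** 2).mean())
        r2 = np.corrcoef(est, ref)[0, 1] ** 2
        assert rep.rmse == pytest.approx(rmse, abs=1e-9)
        assert rep.bias == pytest.approx(bias, abs=1e-9)
        assert rep.rmse_bc == pytest.approx(rmse_bc, abs=1e-9)
        assert rep.r2 == pytest.approx(r2, abs=1e-9)
        # decomposition: RMSE^2 = bias^2 + RMSE_bc^2
        assert rep.rmse**2 == pytest.approx(rep.bias**2 + rep.rmse_bc**2)

    def test_width_uses_closer_of_width_and_thickness(self):
        bbox = BoundingBox(0, 0, 50, 60)
        meas = [FruitMeasurement("f", bbox, 2000.0, length_mm=100, width_mm=74.0)]
        truth = [FruitTruth(0, bbox, 100, 81.0, 2000.0, True)]
        rep = evaluate_measurements(
            meas, truth, dimension="width", thickness_mm={0: 73.0}
        )
        assert rep.residuals[0] == pytest.approx(74.0 - 73.0)

    def test_no_matches_empty_report(self):
        meas = [
            FruitMeasurement(
                "f", BoundingBox(0, 0, 10, 10), 2000.0, length_mm=1, width_mm=1
            )
        ]
        truth = [FruitTruth(0, BoundingBox(200, 200, 260, 260), 100, 80, 2000.0, True)]
        rep = evaluate_measurements(meas, truth)
        assert rep.empty and rep.n_matched == 0

    def test_precision_fraction(self):
        assert precision(353, 435) == pytest.approx(0.8115, abs=1e-4)
        assert precision(90, 90) == 1.0
        with pytest.raises(ValueError):
            precision(1, 0)
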