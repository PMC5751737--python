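"""Otsu split, chroma gate, area morphology and the 1D stalk filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.measure import label

from mangosize.detection import BoundingBox
from mangosize.segmentation import (
    SegmentationConfig,
    chroma_filter,
    expand_box,
    morph_clean,
    otsu_binarize,
    remove_stalks,
    run_filter_line,
    to_cielab,
)
from mangosize.synthetic import _ellipse_mask


def brute_force_otsu(channel, n_bins=256, value_range=(0.0, 100.0)):
    """Exhaustive search over all candidate thresholds (independent oracle)."""
    edges = np.linspace(*value_range, n_bins + 1)
    hist, _ = np.histogram(np.clip(channel, *value_range), bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_k, best_var = 0, -1.0
    total = hist.sum()
    for k in range(n_bins - 1):
        w0 = hist[: k + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: k + 1] * centers[: k + 1]).sum() / w0
        mu1 = (hist[k + 1 :] * centers[k + 1 :]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var + 1e-9:  # ties break toward the lower threshold
            best_var, best_k = var, k
    return float(edges[best_k + 1])


class TestExpandBox:
    def test_doubling_with_clip(self):
        box = BoundingBox(10, 10, 30, 40)
        out = expand_box(box, 2.0, (1000, 1000))
        assert (out.x0, out.y0, out.x1, out.y1) == (0, 0, 40, 55)

    def test_factor_one_identity(self):
        box = BoundingBox(10, 10, 30, 40)
        assert expand_box(box, 1.0, (100, 100)) == box

    def test_far_corner_clips_never_inverts(self):
        box = BoundingBox(90, 90, 99, 99)
        out = expand_box(box, 3.0, (100, 100))
        assert 0 <= out.x0 < out.x1 <= 100
        assert 0 <= out.y0 < out.y1 <= 100


class TestCielab:
    @pytest.mark.parametrize(
        "rgb, L, ab_tol",
        [((255, 255, 255), 100.0, 0.5), ((0, 0, 0), 0.0, 0.5), ((128, 128, 128), None, 0.5)],
    )
    def test_neutral_axis(self, rgb, L, ab_tol):
        lab = to_cielab(np.full((2, 2, 3), rgb, dtype=np.uint8))
        if L is not None:
            assert lab[..., 0] == pytest.approx(L, abs=0.1)
        assert np.all(np.abs(lab[..., 1]) < ab_tol)
        assert np.all(np.abs(lab[..., 2]) < ab_tol)


class TestOtsu:
    def test_two_delta_populations(self):
        ch = np.concatenate([np.full(100, 20.0), np.full(60, 80.0)]).reshape(16, 10)
        thr, mask, degenerate = otsu_binarize(ch)
        assert not degenerate
        np.testing.assert_array_equal(mask, ch == 80.0)

    def test_constant_channel_degenerate(self):
        thr, mask, degenerate = otsu_binarize(np.full((8, 8), 42.0))
        assert degenerate
        assert not mask.any()

    def test_matches_bruteforce_on_random_channels(self, rng):
        for _ in range(50):
            n_modes = rng.integers(2, 5)
            parts = [
                rng.normal(rng.uniform(5, 95), rng.uniform(1, 15), rng.integers(20, 200))
                for _ in range(n_modes)
            ]
            ch = np.clip(np.concatenate(parts), 0, 100)
            thr, _, _ = otsu_binarize(ch)
            assert thr == pytest.approx(brute_force_otsu(ch), abs=1e-12)


class TestChromaFilter:
    def _lab(self, a, b, L=70.0):
        lab = np.zeros((1, 1, 3))
        lab[..., 0], lab[..., 1], lab[..., 2] = L, a, b
        return lab

    @pytest.mark.parametrize(
        "a, b, kept",
        [
            (0, 0, True),
            (30, 0, False),     # a* above the gate
            (25, 35, True),     # inclusive boundary
            (-25, -20, True),   # inclusive boundary, low side
            (-26, 0, False),
            (0, 36, False),
            (0, -21, False),
        ],
    )
    def test_gate(self, a, b, kept):
        cfg = SegmentationConfig()
        mask = np.ones((1, 1), bool)
        out = chroma_filter(self._lab(a, b), mask, cfg)
        assert out[0, 0] == kept

    def test_only_clears_pixels(self, rng):
        lab = np.stack(
            [rng.uniform(0, 100, (20, 20)), rng.uniform(-60, 60, (20, 20)),
             rng.uniform(-60, 60, (20, 20))], axis=-1,
        )
        mask = rng.random((20, 20)) < 0.5
        out = chroma_filter(lab, mask, SegmentationConfig())
        assert not np.any(out & ~mask)


class TestMorphClean:
    def test_299_px_blob_removed_300_kept(self):
        mask = np.zeros((60, 60), bool)
        mask[5:25, 5:20] = True  # 300 px
        assert morph_clean(mask, 300).sum() == 300
        mask[5, 5] = False  # 299 px
        assert morph_clean(mask, 300).sum() == 0

    def test_hole_filled_exact_count(self):
        mask = np.zeros((120, 120), bool)
        mask[10:90, 10:80] = True
        mask[30:55, 30:40] = False  # 250-px hole
        before = mask.sum()
        out = morph_clean(mask, 300)
        assert out.sum() == before + 250

    def test_postcondition_no_small_components_or_holes(self, rng):
        for _ in range(10):
            mask = rng.random((80, 80)) < 0.55
            out = morph_clean(mask, 300)
            comps = label(out, connectivity=2)
            for i in range(1, comps.max() + 1):
                assert (comps == i).sum() >= 300
            holes = label(~out & ~_border_background(out), connectivity=1)
            for i in range(1, holes.max() + 1):
                assert (holes == i).sum() >= 300


def _border_background(mask):
    """Background pixels connected to the border (not holes)."""
    from scipy import ndimage

    bg = ~mask
    lab, _ = ndimage.label(bg, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    border_labels = np.unique(
        np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
    )
    return np.isin(lab, border_labels[border_labels > 0])


class TestRunFilter:
    @pytest.mark.parametrize(
        "values, w, expected",
        [
            ([0, 1, 1, 1, 1, 1, 1, 1, 0], 8, [0] * 9),          # run of 7 < w
            ([0] + [1] * 8 + [0], 8, [0] + [1] * 8 + [0]),       # run of 8 kept
            ([1, 1, 1], 8, [0, 0, 0]),                           # border delimits
            ([1] * 8, 8, [1] * 8),
            ([0, 2, 3, 0, 5, 5, 5, 5, 0], 4, [0, 0, 0, 0, 5, 5, 5, 5, 0]),
        ],
    )
    def test_rule(self, values, w, expected):
        np.testing.assert_array_equal(run_filter_line(np.array(values), w), expected)

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=60), st.integers(1, 10))
    @settings(deadline=None, max_examples=100)
    def test_idempotent(self, values, w):
        v = np.array(values)
        once = run_filter_line(v, w)
        np.testing.assert_array_equal(run_filter_line(once, w), once)


class TestRemoveStalks:
    def test_stalk_removed_fruit_preserved(self):
        cfg = SegmentationConfig()
        body = _ellipse_mask((120, 100), 50, 70, 20, 30, 0.0)
        stalk = np.zeros_like(body)
        stalk[10:42, 49:52] = True  # 3-px-wide, ~30-px-long vertical stalk
        mask = body | stalk
        out = remove_stalks(mask, cfg)
        # stalk gone (beyond the 1-px dilation band of the fruit)
        assert not out[10:35, 49:52].any()
        # fruit preserved up to the dilation band
        assert (body & ~out).sum() == 0

    def test_no_short_runs_equals_dilation_only(self):
        from skimage.morphology import dilation, disk

        cfg = SegmentationConfig()
        mask = np.zeros((60, 60), bool)
        mask[10:40, 10:40] = True  # all runs >= 30 > w
        out = remove_stalks(mask, cfg)
        np.testing.assert_array_equal(out, dilation(mask, disk(1)))

    def test_empty_mask(self):
        out = remove_stalks(np.zeros((20, 20), bool), SegmentationConfig())
        assert not out.any()

    def test_never_creates_foreground_outside_dilation_band(self, rng):
        from skimage.morphology import dilation, disk

        cfg = SegmentationConfig()
        for _ in range(5):
            mask = rng.random((50, 50)) < 0.4
            out = remove_stalks(mask, cfg)
            assert not np.any(out & ~dilation(mask, disk(cfg.dilation_radius)))
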