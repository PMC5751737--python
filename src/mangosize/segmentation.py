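"""Pixel-level background removal and stalk filtering.

Under night LED illumination a convex, waxy mango reflects more light than
the surrounding foliage, so within an (expanded) detection box the fruit is
the bright class of an Otsu split on L*.  Residual leaf/branch pixels are
removed with a fixed chroma gate in CIELAB (-25 <= a* <= 25, -20 <= b* <= 35),
small objects and holes (< 300 px) are cleaned up, and the thin pendulous
stalk is erased by a 1D run-length filter applied row-wise then column-wise,
followed by a radius-1 disk dilation that restores the fruit tip the filter
may clip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color as _skcolor
from skimage import morphology as _skmorph

from .detection import BoundingBox

__all__ = [
    "SegmentationConfig",
    "FruitCandidate",
    "expand_box",
    "to_cielab",
    "otsu_binarize",
    "chroma_filter",
    "morph_clean",
    "run_filter_line",
    "remove_stalks",
    "segment_candidate",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds of the segmentation stage.

    ``a_range``/``b_range`` are the inclusive CIELAB chroma gates for fruit;
    ``min_area`` the area-opening/hole-filling size in pixels; ``stalk_w`` the
    1D run-length threshold (8 px is roughly 14 mm at a 2 m working
    distance); ``dilation_radius`` the compensating disk dilation.
    """

    box_expand_factor: float = 2.0
    a_range: tuple[float, float] = (-25.0, 25.0)
    b_range: tuple[float, float] = (-20.0, 35.0)
    min_area: int = 300
    stalk_w: int = 8
    dilation_radius: int = 1

    def __post_init__(self) -> None:
        if self.a_range[0] > self.a_range[1] or self.b_range[0] > self.b_range[1]:
            raise ValueError("chroma ranges must be well ordered")
        if self.min_area <= 0:
            raise ValueError("min_area must be positive")
        if self.stalk_w < 1:
            raise ValueError("stalk_w must be >= 1")


@dataclass
class FruitCandidate:
    """One detection box with its expanded snip and evolving mask."""

    source_box: BoundingBox
    expanded_box: BoundingBox
    snip: np.ndarray
    mask: np.ndarray | None = None
    rejection_reason: str | None = None
    provenance: dict = field(default_factory=dict)


def expand_box(
    box: BoundingBox, factor: float, raster_bounds: tuple[int, int]
) -> BoundingBox:
    """Scale a box about its centre by ``factor``, then clip to the raster.

    ``raster_bounds`` is ``(width, height)``.  The default doubling ensures
    the expanded snip covers the whole fruit even when the detector box is
    tight or off-centre.
    """
    if factor < 1:
        raise ValueError("expansion factor must be >= 1")
    w, h = box.x1 - box.x0, box.y1 - box.y0
    cx, cy = (box.x0 + box.x1) / 2.0, (box.y0 + box.y1) / 2.0
    nw, nh = w * factor, h * factor
    x0 = int(round(cx - nw / 2.0))
    x1 = int(round(cx + nw / 2.0))
    y0 = int(round(cy - nh / 2.0))
    y1 = int(round(cy + nh / 2.0))
    W, H = raster_bounds
    return BoundingBox(max(0, x0), max(0, y0), min(W, x1), min(H, y1))


def to_cielab(rgb_snip: np.ndarray) -> np.ndarray:
    """Convert an 8-bit sRGB snip to CIELAB (D65), L* on [0, 100]."""
    rgb = np.asarray(rgb_snip)
    if rgb.dtype != np.uint8:
        raise ValueError("expected 8-bit RGB input")
    return _skcolor.rgb2lab(rgb.astype(float) / 255.0)


def otsu_binarize(
    channel: np.ndarray, *, n_bins: int = 256, value_range: tuple[float, float] = (0.0, 100.0)
) -> tuple[float, np.ndarray, bool]:
    """Otsu threshold on a 256-bin histogram; bright class is foreground.

    Returns ``(threshold, mask, degenerate)``.  The threshold maximises the
    between-class variance (equivalently minimises intra-class variance);
    ties break toward the lower threshold.  A constant channel is degenerate
    and yields an empty mask.
    """
    ch = np.asarray(channel, dtype=float)
    lo, hi = value_range
    if np.all(ch == ch.flat[0]):
        return float(ch.flat[0]), np.zeros(ch.shape, dtype=bool), True
    edges = np.linspace(lo, hi, n_bins + 1)
    hist, _ = np.histogram(np.clip(ch, lo, hi), bins=edges)
    p = hist.astype(float) / hist.sum()
    omega = np.cumsum(p)
    centers = (edges[:-1] + edges[1:]) / 2.0
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    # between-class variance for a split after bin k
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    k = int(np.argmax(sigma_b))  # argmax takes the first (lowest) maximiser
    threshold = float(edges[k + 1])
    mask = ch > threshold
    return threshold, mask, False


def chroma_filter(
    lab_snip: np.ndarray, mask: np.ndarray, config: SegmentationConfig
) -> np.ndarray:
    """Clear mask pixels whose a*/b* chroma falls outside the fruit gate.

    Both bounds are inclusive and the a* and b* conditions must hold
    simultaneously.  The filter only ever removes pixels.
    """
    a = lab_snip[..., 1]
    b = lab_snip[..., 2]
    a_lo, a_hi = config.a_range
    b_lo, b_hi = config.b_range
    keep = (a >= a_lo) & (a <= a_hi) & (b >= b_lo) & (b <= b_hi)
    return mask & keep


def morph_clean(mask: np.ndarray, min_area: int = 300) -> np.ndarray:
    """Area opening then hole filling, both with a strict ``< min_area`` rule.

    Foreground components use 8-connectivity, holes 4-connectivity (the
    standard dual pairing).  A 299-px blob disappears; a 300-px blob stays.
    """
    mask = np.asarray(mask, dtype=bool)
    # max_size removes/fills components of area <= max_size, so min_area - 1
    # gives the strict "< min_area" rule.
    opened = _skmorph.remove_small_objects(mask, max_size=min_area - 1, connectivity=2)
    filled = _skmorph.remove_small_holes(opened, max_size=min_area - 1, connectivity=1)
    return filled


def run_filter_line(values: np.ndarray, w: int) -> np.ndarray:
    """Zero every maximal non-zero run shorter than ``w``; line ends count as
    zero delimiters."""
    if w < 1:
        raise ValueError("w must be >= 1")
    v = np.asarray(values)
    nz = v != 0
    if not nz.any():
        return np.zeros_like(v)
    padded = np.concatenate([[False], nz, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    out = v.copy()
    for s, e in zip(starts, ends):
        if e - s < w:
            out[s:e] = 0
    return out


def _run_filter_axis(mask: np.ndarray, w: int, axis: int) -> np.ndarray:
    """Vectorised run filter along one axis of a 2D boolean mask."""
    m = mask if axis == 1 else mask.T
    rows, cols = m.shape
    padded = np.zeros((rows, cols + 2), dtype=bool)
    padded[:, 1:-1] = m
    diff = np.diff(padded.astype(np.int8), axis=1)
    out = m.copy()
    rs, cs = np.nonzero(diff == 1)
    re, ce = np.nonzero(diff == -1)
    # starts and ends pair up in order within each row
    for r, s, e in zip(rs, cs, ce):
        if e - s < w:
            out[r, s:e] = False
    return out if axis == 1 else out.T


def remove_stalks(mask: np.ndarray, config: SegmentationConfig) -> np.ndarray:
    """1D stalk filter: horizontal pass, vertical pass, then disk dilation.

    Stalks hang vertically under the fruit's weight, so the horizontal pass
    removes them (their row-wise runs are thin); the vertical pass catches
    leaves or stalks touching the fruit's side.  Being line-based, the filter
    preserves the fruit's overall shape, and a radius-1 dilation restores the
    sharp fruit tip the filter can truncate.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    w = config.stalk_w
    filtered = _run_filter_axis(mask, w, axis=1)
    filtered = _run_filter_axis(filtered, w, axis=0)
    if config.dilation_radius > 0:
        filtered = _skmorph.dilation(
            filtered, _skmorph.disk(config.dilation_radius)
        )
    return filtered


def segment_candidate(
    snip_rgb: np.ndarray, config: SegmentationConfig | None = None
) -> tuple[np.ndarray, dict]:
    """Full segmentation of one expanded snip.

    Order: Otsu on L* -> chroma gate -> area opening -> hole filling ->
    stalk filter -> dilation.  Returns the binary mask and a provenance dict
    (threshold used, pixel counts after each stage, degenerate flag).
    """
    config = config or SegmentationConfig()
    lab = to_cielab(snip_rgb)
    threshold, mask, degenerate = otsu_binarize(lab[..., 0])
    prov: dict = {"otsu_threshold": threshold, "otsu_degenerate": degenerate}
    prov["px_otsu"] = int(mask.sum())
    if degenerate:
        return mask, prov
    mask = chroma_filter(lab, mask, config)
    prov["px_chroma"] = int(mask.sum())
    mask = morph_clean(mask, config.min_area)
    prov["px_morph"] = int(mask.sum())
    mask = remove_stalks(mask, config)
    prov["px_stalk"] = int(mask.sum())
    return mask, prov
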