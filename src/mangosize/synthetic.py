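"""Synthetic night-orchard RGB-D scenes with known ground truth.

The generator emulates the imaging conditions the pipeline is built for:
bright convex elliptical fruit against darker foliage (LED-illuminated night
canopy), thin pendulous stalks, partial occlusions by leaves, camera-to-
fruit distances of 1-3 m, and integer-millimetre depth with Gaussian sensor
noise (default sigma 11 mm, the depth error level measured on fruit for the
ToF unit).  Scenes are composed in CIELAB so fruit chroma lands inside the
segmentation gate (|a*| <= 15, 0 <= b* <= 25) and foliage chroma outside it
(a* <= -30 or b* >= 45), then converted to 8-bit sRGB.

Also provides the evaluation metrics used to score measurements against
truth or caliper data: RMSE, bias, bias-corrected RMSE, R^2 and detection
precision, with machine-vision widths compared against the closer of the
manual width and thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color as _skcolor

from .allometry import width_reference
from .camera import CameraIntrinsics, Extrinsics, KINECT_RGB, RGBDFrame, mm_to_pixels
from .detection import BoundingBox

__all__ = [
    "FruitSpec",
    "SceneSpec",
    "SceneParams",
    "FruitTruth",
    "EvalReport",
    "default_scene_intrinsics",
    "sample_scene",
    "render_scene",
    "make_training_snips",
    "evaluate_measurements",
    "precision",
]

# night-scene CIELAB palette (see module docstring)
_BG_LAB = (12.0, 0.0, 5.0)
_FRUIT_L = (65.0, 80.0)
_FRUIT_A = (-15.0, 15.0)
_FRUIT_B = (0.0, 25.0)
_LEAF_L = (25.0, 45.0)


def default_scene_intrinsics(resolution: tuple[int, int] = (360, 360)) -> CameraIntrinsics:
    """Table-style RGB optics behind a small centred raster (a crop-sized
    frame that keeps rendered scenes compact)."""
    return KINECT_RGB.with_resolution(resolution)


@dataclass(frozen=True)
class FruitSpec:
    """One fruit: 3D centre in camera coordinates (mm) and true dimensions."""

    center_mm: tuple[float, float, float]
    length_mm: float
    width_mm: float
    tilt_rad: float = 0.0
    occlusion_fraction: float = 0.0
    stalk_width_px: int = 3
    stalk_length_px: int = 25

    def __post_init__(self) -> None:
        if not (0.0 <= self.occlusion_fraction < 1.0):
            raise ValueError("occlusion fraction must be in [0, 1)")
        if self.length_mm <= 0 or self.width_mm <= 0:
            raise ValueError("fruit dimensions must be positive")


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic scene (deterministic given seed)."""

    fruits: tuple[FruitSpec, ...]
    leaf_density: float = 2.5e-4
    illumination_gradient: float = 5.0
    depth_noise_sigma: float = 11.0
    dropout_fraction: float = 0.0
    seed: int = 0
    frame_id: str = "synthetic"


@dataclass(frozen=True)
class SceneParams:
    """Sampling ranges for random scenes (the study conditions).

    Fruit lengths 60-160 mm and widths 50-130 mm span a typical cultivar
    from stone hardening to harvest; distances 1000-3000 mm are the working
    camera-to-fruit range.
    """

    n_fruit: int = 5
    distance_range_mm: tuple[float, float] = (1000.0, 3000.0)
    length_range_mm: tuple[float, float] = (60.0, 160.0)
    width_range_mm: tuple[float, float] = (50.0, 130.0)
    #: imaged width over length; mango are longer than wide (a typical fruit
    #: images ~70x50 px at 2 m), so width is sampled as a fraction of length
    #: and clipped to the width range
    aspect_range: tuple[float, float] = (0.72, 0.88)
    occluded_probability: float = 0.0
    occlusion_range: tuple[float, float] = (0.2, 0.5)
    leaf_density: float = 2.5e-4
    illumination_gradient: float = 5.0
    depth_noise_sigma: float = 11.0
    dropout_fraction: float = 0.0
    intrinsics: CameraIntrinsics = field(default_factory=default_scene_intrinsics)


@dataclass
class FruitTruth:
    """Ground truth for one rendered fruit."""

    fruit_id: int
    bbox: BoundingBox
    length_mm: float
    width_mm: float
    distance_mm: float
    un_occluded: bool
    occlusion_fraction: float = 0.0


@dataclass
class EvalReport:
    """Agreement between measurements and reference values."""

    n_matched: int
    rmse: float
    bias: float
    rmse_bc: float
    r2: float
    precision: float
    residuals: np.ndarray
    empty: bool = False


# ---------------------------------------------------------------------------
# Scene sampling


def sample_scene(params: SceneParams, seed: int) -> SceneSpec:
    """Sample a random scene spec; fruit are placed so their full extent
    (plus stalk) is inside the frame and fruit do not overlap each other."""
    if params.n_fruit < 0:
        raise ValueError("n_fruit must be >= 0")
    lo, hi = params.distance_range_mm
    if not 0 < lo < hi:
        raise ValueError("impossible distance range")
    rng = np.random.default_rng(seed)
    intr = params.intrinsics
    cols, rows = intr.resolution
    cx, cy = intr.principal_point
    fruits: list[FruitSpec] = []
    boxes: list[tuple[float, float, float, float]] = []
    for _ in range(params.n_fruit):
        for _attempt in range(200):
            Z = rng.uniform(*params.distance_range_mm)
            L = rng.uniform(*params.length_range_mm)
            W = float(
                np.clip(L * rng.uniform(*params.aspect_range), *params.width_range_mm)
            )
            sy = mm_to_pixels(L / 2.0, Z, intr.focal_y, intr.pixel_pitch)
            sx = mm_to_pixels(W / 2.0, Z, intr.focal_x, intr.pixel_pitch)
            stalk_len = int(rng.integers(15, 35))
            margin_y = sy + stalk_len + 4
            margin_x = sx + 4
            if 2 * margin_x >= cols or 2 * margin_y >= rows:
                continue
            u = rng.uniform(margin_x, cols - margin_x)
            v = rng.uniform(margin_y, rows - margin_y)
            cand = (u - sx - 6, v - sy - stalk_len - 6, u + sx + 6, v + sy + 6)
            if any(
                cand[0] < b[2] and b[0] < cand[2] and cand[1] < b[3] and b[1] < cand[3]
                for b in boxes
            ):
                continue
            occ = 0.0
            if rng.random() < params.occluded_probability:
                occ = float(rng.uniform(*params.occlusion_range))
            X = (u - cx) / intr.fx_px * Z
            Y = (v - cy) / intr.fy_px * Z
            fruits.append(
                FruitSpec(
                    center_mm=(X, Y, Z),
                    length_mm=L,
                    width_mm=W,
                    tilt_rad=float(rng.uniform(-0.12, 0.12)),
                    occlusion_fraction=occ,
                    stalk_width_px=int(rng.integers(2, 5)),
                    stalk_length_px=stalk_len,
                )
            )
            boxes.append(cand)
            break
    return SceneSpec(
        fruits=tuple(fruits),
        leaf_density=params.leaf_density,
        illumination_gradient=params.illumination_gradient,
        depth_noise_sigma=params.depth_noise_sigma,
        dropout_fraction=params.dropout_fraction,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Rendering


def _ellipse_mask(
    shape: tuple[int, int], cx: float, cy: float, sx: float, sy: float, theta: float
) -> np.ndarray:
    """Boolean mask of a filled rotated ellipse (pixel-centre sampling)."""
    rows, cols = shape
    y0 = max(0, int(cy - sy - sx - 2))
    y1 = min(rows, int(cy + sy + sx + 3))
    x0 = max(0, int(cx - sx - sy - 2))
    x1 = min(cols, int(cx + sx + sy + 3))
    out = np.zeros(shape, dtype=bool)
    if y1 <= y0 or x1 <= x0:
        return out
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx - cx
    dy = yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    out[y0:y1, x0:x1] = (u / sx) ** 2 + (v / sy) ** 2 <= 1.0
    return out


def _occluder_mask(
    body: np.ndarray,
    fraction: float,
    cx: float,
    cy: float,
    body_sx: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Elliptical occluder covering ``fraction`` of the fruit's pixels.

    The occluder approaches from the left or right; its in-travel position is
    found by bisection so the covered fraction matches the request.
    """
    side = 1.0 if rng.random() < 0.5 else -1.0
    occ_sx = body_sx * 1.0
    occ_sy = body_sx * 1.4
    theta = rng.uniform(-0.3, 0.3)
    target = fraction * body.sum()
    start = cx - side * (body_sx + occ_sx)  # just outside: zero overlap
    end = cx
    lo, hi = 0.0, 1.0
    for _ in range(40):
        mid = (lo + hi) / 2.0
        occ = _ellipse_mask(
            body.shape, start + mid * (end - start), cy, occ_sx, occ_sy, theta
        )
        if (body & occ).sum() < target:
            lo = mid
        else:
            hi = mid
    return _ellipse_mask(
        body.shape, start + hi * (end - start), cy, occ_sx, occ_sy, theta
    )


def render_scene(
    spec: SceneSpec,
    rgb_intr: CameraIntrinsics | None = None,
    depth_intr: CameraIntrinsics | None = None,
    ext: Extrinsics | None = None,
    *,
    registered: bool = True,
) -> tuple[RGBDFrame, list[FruitTruth]]:
    """Render a scene to an RGB-D frame plus per-fruit ground truth.

    By default the depth raster is rendered pixel-aligned with the RGB
    raster (registered geometry).  With ``registered=False`` the depth is
    rendered through ``depth_intr`` and ``ext`` (depth-camera to RGB-camera
    transform) to exercise the registration path; fruit 3D centres are
    interpreted in RGB-camera coordinates in both modes.

    Fruit whose projection falls outside the frame are dropped from the
    truth list.  Depth on fruit carries the true distance plus truncated
    Gaussian noise (sigma = ``spec.depth_noise_sigma``), quantised to
    integer mm, with optional dropout to 0.
    """
    rgb_intr = rgb_intr or default_scene_intrinsics()
    cols, rows = rgb_intr.resolution
    rng = np.random.default_rng(spec.seed)

    L_ch = np.full((rows, cols), _BG_LAB[0], dtype=float)
    a_ch = np.full((rows, cols), _BG_LAB[1], dtype=float)
    b_ch = np.full((rows, cols), _BG_LAB[2], dtype=float)
    # background texture so Otsu sees a genuine dark class
    L_ch += rng.normal(0.0, 1.5, size=L_ch.shape)
    depth = np.zeros((rows, cols), dtype=np.int32)

    # foliage clutter first; fruit are drawn over it so clutter never
    # occludes fruit unless explicitly requested per fruit
    n_leaves = int(round(spec.leaf_density * rows * cols))
    for _ in range(n_leaves):
        lx = rng.uniform(0, cols)
        ly = rng.uniform(0, rows)
        m = _ellipse_mask(
            (rows, cols), lx, ly, rng.uniform(8, 30), rng.uniform(5, 16),
            rng.uniform(0, np.pi),
        )
        L_ch[m] = rng.uniform(*_LEAF_L)
        if rng.random() < 0.5:
            a_ch[m] = rng.uniform(-60, -35)
            b_ch[m] = rng.uniform(10, 30)
        else:
            a_ch[m] = rng.uniform(-10, 10)
            b_ch[m] = rng.uniform(45, 70)
        depth[m] = int(rng.uniform(1200, 3400))

    cx0, cy0 = rgb_intr.principal_point
    truths: list[FruitTruth] = []
    for i, fr in enumerate(spec.fruits):
        X, Y, Z = fr.center_mm
        u = X / Z * rgb_intr.fx_px + cx0
        v = Y / Z * rgb_intr.fy_px + cy0
        sy = mm_to_pixels(fr.length_mm / 2.0, Z, rgb_intr.focal_y, rgb_intr.pixel_pitch)
        sx = mm_to_pixels(fr.width_mm / 2.0, Z, rgb_intr.focal_x, rgb_intr.pixel_pitch)
        body = _ellipse_mask((rows, cols), u, v, sx, sy, fr.tilt_rad)
        if not body.any() or u - sx < 0 or u + sx >= cols or v - sy < 0 or v + sy >= rows:
            continue  # projects (partly) outside the frame: drop with no truth
        fruit_L = rng.uniform(*_FRUIT_L)
        L_ch[body] = fruit_L + rng.normal(0.0, 0.8, size=int(body.sum()))
        a_ch[body] = rng.uniform(*_FRUIT_A)
        b_ch[body] = rng.uniform(*_FRUIT_B)

        ys, xs = np.nonzero(body)
        bbox = BoundingBox(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)

        # pendulous stalk: a thin vertical strip rising from the fruit top,
        # same chroma family as fruit so only the run-length filter removes it
        sw = max(1, fr.stalk_width_px)
        half = sw // 2
        top = int(ys.min())
        x_lo = int(round(u)) - half
        x_hi = x_lo + sw
        y_lo = max(0, top - fr.stalk_length_px)
        stalk = np.zeros_like(body)
        stalk[y_lo:top + 2, max(0, x_lo):min(cols, x_hi)] = True
        stalk &= ~body
        L_ch[stalk] = fruit_L - 8.0
        a_ch[stalk] = 5.0
        b_ch[stalk] = 15.0

        fruit_px = body | stalk
        true_depth = np.full(int(fruit_px.sum()), Z)
        if spec.depth_noise_sigma > 0:
            noise = rng.normal(0.0, spec.depth_noise_sigma, size=true_depth.shape)
            lim = 3.0 * spec.depth_noise_sigma
            noise = np.clip(noise, -lim, lim)
            true_depth = true_depth + noise
        depth[fruit_px] = np.round(true_depth).astype(np.int32)

        occluded = fr.occlusion_fraction > 0
        if occluded:
            # an elliptical leaf in front of the fruit, slid in from one side
            # until it covers the requested fraction of the fruit's pixels;
            # the bite it takes is concave, as a real leaf edge would be
            occ = _occluder_mask(body, fr.occlusion_fraction, u, v, sx, rng)
            L_ch[occ] = rng.uniform(*_LEAF_L)
            a_ch[occ] = rng.uniform(-60, -35)
            b_ch[occ] = rng.uniform(10, 30)
            depth[occ] = int(Z - 150)

        truths.append(
            FruitTruth(
                fruit_id=i,
                bbox=bbox,
                length_mm=fr.length_mm,
                width_mm=fr.width_mm,
                distance_mm=float(Z),
                un_occluded=not occluded,
                occlusion_fraction=fr.occlusion_fraction,
            )
        )

    if spec.illumination_gradient:
        grad = np.linspace(0.0, spec.illumination_gradient, rows)[:, None]
        L_ch = L_ch + grad
    lab = np.stack([np.clip(L_ch, 0, 100), a_ch, b_ch], axis=-1)
    rgb = np.clip(_skcolor.lab2rgb(lab), 0.0, 1.0)
    rgb8 = np.round(rgb * 255.0).astype(np.uint8)

    if spec.dropout_fraction > 0:
        drop = rng.random(depth.shape) < spec.dropout_fraction
        depth[drop] = 0

    if registered:
        frame = RGBDFrame(
            rgb=rgb8, depth=depth, registered=True, frame_id=spec.frame_id
        )
        return frame, truths

    # unregistered mode: re-render depth through the depth camera's own
    # geometry so the registration path has real work to do
    if depth_intr is None or ext is None:
        raise ValueError("unregistered rendering needs depth_intr and ext")
    dcols, drows = depth_intr.resolution
    ddepth = np.zeros((drows, dcols), dtype=np.int32)
    R_inv = ext.rotation.T
    t = ext.translation
    dcx, dcy = depth_intr.principal_point
    for fr in spec.fruits:
        p_rgb = np.asarray(fr.center_mm, dtype=float)
        p_d = R_inv @ (p_rgb - t)  # back into depth-camera coordinates
        if p_d[2] <= 0:
            continue
        ud = p_d[0] / p_d[2] * depth_intr.fx_px + dcx
        vd = p_d[1] / p_d[2] * depth_intr.fy_px + dcy
        sy = mm_to_pixels(fr.length_mm / 2.0, p_d[2], depth_intr.focal_y, depth_intr.pixel_pitch)
        sx = mm_to_pixels(fr.width_mm / 2.0, p_d[2], depth_intr.focal_x, depth_intr.pixel_pitch)
        m = _ellipse_mask((drows, dcols), ud, vd, sx, sy, fr.tilt_rad)
        ddepth[m] = int(round(p_d[2]))
    frame = RGBDFrame(rgb=rgb8, depth=ddepth, registered=False, frame_id=spec.frame_id)
    return frame, truths


# ---------------------------------------------------------------------------
# Training snips


def make_training_snips(
    n_pos: int, n_neg: int, seed: int = 0, window: int = 48
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Generate labelled snips for cascade training.

    Positives are bright fruit ellipses roughly filling the window over dark
    backgrounds; negatives are foliage texture, leaf blobs or plain
    background at night levels.
    """
    rng = np.random.default_rng(seed)
    pos: list[np.ndarray] = []
    neg: list[np.ndarray] = []

    def _to_rgb(L, a, b):
        lab = np.stack([np.clip(L, 0, 100), a, b], axis=-1)
        return np.round(np.clip(_skcolor.lab2rgb(lab), 0, 1) * 255).astype(np.uint8)

    def _bg(shape):
        L = np.full(shape, _BG_LAB[0]) + rng.normal(0, 1.5, shape)
        a = np.full(shape, _BG_LAB[1], dtype=float)
        b = np.full(shape, _BG_LAB[2], dtype=float)
        return L, a, b

    def _paint_leaf(L, a, b, c):
        m = _ellipse_mask(
            L.shape, rng.uniform(0, c), rng.uniform(0, c),
            rng.uniform(0.1 * c, 0.5 * c), rng.uniform(0.08 * c, 0.35 * c),
            rng.uniform(0, np.pi),
        )
        L[m] = rng.uniform(*_LEAF_L)
        if rng.random() < 0.5:
            a[m] = rng.uniform(-60, -35)
            b[m] = rng.uniform(10, 30)
        else:
            a[m] = rng.uniform(-10, 10)
            b[m] = rng.uniform(45, 70)

    # snips are rendered on a random-size canvas and later resized down to
    # the model window; this bakes the pyramid's resampling blur into the
    # training distribution
    for _ in range(n_pos):
        c = int(rng.integers(40, 150))
        L, a, b = _bg((c, c))
        Lmm = rng.uniform(60.0, 160.0)
        Wmm = Lmm * rng.uniform(0.7, 0.9)
        fill = rng.uniform(0.8, 0.95)
        sy = c / 2.0 * fill
        sx = sy * Wmm / Lmm
        jit = 0.07 * c
        cx = c / 2.0 + rng.uniform(-jit, jit)
        cy = c / 2.0 + rng.uniform(-jit, jit)
        m = _ellipse_mask((c, c), cx, cy, sx, sy, rng.uniform(-0.15, 0.15))
        fruit_L = rng.uniform(*_FRUIT_L)
        L[m] = fruit_L + rng.normal(0, 0.8, int(m.sum()))
        a[m] = rng.uniform(*_FRUIT_A)
        b[m] = rng.uniform(*_FRUIT_B)
        if rng.random() < 0.5:  # pendulous stalk above the fruit
            sw = max(2, int(round(c / 16.0)))
            x_lo = int(cx) - sw // 2
            top = max(0, int(cy - sy))
            stalk = np.zeros_like(m)
            stalk[: top + 2, max(0, x_lo) : min(c, x_lo + sw)] = True
            stalk &= ~m
            L[stalk] = fruit_L - 8.0
            a[stalk] = 5.0
            b[stalk] = 15.0
        pos.append(_to_rgb(L, a, b))

    for _ in range(n_neg):
        c = int(rng.integers(40, 150))
        L, a, b = _bg((c, c))
        kind = int(rng.integers(0, 4))
        if kind >= 1:  # leaf blobs, foliage clusters, partial leaves at border
            for _k in range(int(rng.integers(1, 5))):
                _paint_leaf(L, a, b, c)
        neg.append(_to_rgb(L, a, b))
    return pos, neg


# ---------------------------------------------------------------------------
# Evaluation metrics


def precision(true_accepted: int, total_accepted: int) -> float:
    """Detection precision: true accepted / total accepted (fraction)."""
    if total_accepted <= 0:
        raise ValueError("total_accepted must be positive")
    return true_accepted / total_accepted


def _agreement(est: np.ndarray, ref: np.ndarray) -> tuple[float, float, float, float]:
    """RMSE, bias, bias-corrected RMSE and squared Pearson correlation."""
    res = est - ref
    bias = float(res.mean())
    rmse = float(np.sqrt(np.mean(res**2)))
    rmse_bc = float(np.sqrt(np.mean((res - bias) ** 2)))
    if est.size < 2 or np.std(est) == 0 or np.std(ref) == 0:
        r2 = 1.0 if rmse_bc == 0 else 0.0
    else:
        r2 = float(np.corrcoef(est, ref)[0, 1] ** 2)
    return rmse, bias, rmse_bc, r2


def evaluate_measurements(
    measurements,
    truths,
    *,
    dimension: str = "length",
    iou_min: float = 0.5,
    thickness_mm=None,
) -> EvalReport:
    """Score measurements against truth (or caliper) records.

    Measurements are matched to truth records by bounding-box overlap
    (IoU > ``iou_min``); each truth record matches at most one measurement.
    ``dimension`` selects length or width residuals; for widths, when
    ``thickness_mm`` maps ``fruit_id`` to a caliper thickness, the reference
    is the closer of the manual width and thickness (uncontrolled fruit
    orientation).  Precision counts accepted measurements whose match is an
    un-occluded truth fruit.
    """
    measurements = list(measurements)
    truths = list(truths)
    if dimension not in ("length", "width"):
        raise ValueError("dimension must be 'length' or 'width'")
    matched_est: list[float] = []
    matched_ref: list[float] = []
    n_true = 0
    used: set[int] = set()
    for m in measurements:
        best, best_iou = None, iou_min
        for j, t in enumerate(truths):
            if j in used:
                continue
            iou = m.bbox.iou(t.bbox)
            if iou > best_iou:
                best, best_iou = j, iou
        if best is None:
            continue
        used.add(best)
        t = truths[best]
        if t.un_occluded:
            n_true += 1
        if dimension == "length":
            matched_est.append(m.length_mm)
            matched_ref.append(t.length_mm)
        else:
            mv = m.width_mm
            if thickness_mm is not None and t.fruit_id in thickness_mm:
                ref = width_reference(t.width_mm, thickness_mm[t.fruit_id], mv)
            else:
                ref = t.width_mm
            matched_est.append(mv)
            matched_ref.append(ref)
    if not matched_est:
        return EvalReport(
            n_matched=0, rmse=float("nan"), bias=float("nan"),
            rmse_bc=float("nan"), r2=float("nan"),
            precision=0.0 if measurements else float("nan"),
            residuals=np.array([]), empty=True,
        )
    est = np.asarray(matched_est, dtype=float)
    ref = np.asarray(matched_ref, dtype=float)
    rmse, bias, rmse_bc, r2 = _agreement(est, ref)
    prec = n_true / len(measurements) if measurements else float("nan")
    return EvalReport(
        n_matched=len(matched_est), rmse=rmse, bias=bias, rmse_bc=rmse_bc,
        r2=r2, precision=prec, residuals=est - ref,
    )
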