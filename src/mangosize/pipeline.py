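"""End-to-end fruit sizing workflow.

Per frame: crop the RGB raster to the depth field of view (identity for
pre-registered frames), mirror (the RGB-D unit streams a mirrored image),
detect candidate fruit, expand each detection box, segment fruit from
background, remove stalks, gate each connected component for completeness,
look up depth at the bounding-box centre and convert pixel extents to
millimetres with the thin-lens relation.  Every detection box is accounted
for exactly once — as an accepted measurement or a rejection with the first
failed criterion.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import label as _sk_label

from .camera import (
    CameraIntrinsics,
    Extrinsics,
    KINECT_RGB,
    RGBDFrame,
    crop_rgb_to_depth_fov,
    register_depth_to_rgb,
)
from .detection import BoundingBox, DetectorModel, detect_fruit, mirror_horizontal
from .ellipse import GateConfig, fit_moment_ellipse, gate_component
from .segmentation import SegmentationConfig, expand_box, segment_candidate
from .sizing import (
    DepthUnavailableError,
    FruitMeasurement,
    SizingConfig,
    measure_component,
)

__all__ = ["PipelineConfig", "FrameResult", "size_frame", "size_batch", "measurements_to_frame"]

#: fixed vocabulary of rejection reasons (auditable)
REJECTION_REASONS = (
    "detector-merge",
    "otsu-degenerate",
    "chroma-empty",
    "area-low",
    "area-high",
    "ratio-low",
    "ecc-high",
    "bbox-major",
    "depth-missing",
    "depth-near",
)


@dataclass
class PipelineConfig:
    """All stage configurations plus workflow flags."""

    rgb_intrinsics: CameraIntrinsics = field(default_factory=lambda: KINECT_RGB)
    depth_intrinsics: CameraIntrinsics | None = None
    extrinsics: Extrinsics | None = None
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    gate: GateConfig = field(default_factory=GateConfig)
    sizing: SizingConfig = field(default_factory=SizingConfig)
    mirror: bool = True
    crop_to_depth_fov: bool = False
    dedupe_overlap: float = 0.5


@dataclass
class FrameResult:
    """Outcome of sizing one frame."""

    frame_id: str
    measurements: list[FruitMeasurement]
    rejections: list[tuple[BoundingBox, str]]
    accepted_boxes: list[BoundingBox] = field(default_factory=list)
    timings: dict = field(default_factory=dict)
    skipped: str | None = None


def size_frame(
    frame: RGBDFrame,
    config: PipelineConfig,
    detector: DetectorModel | callable,
) -> FrameResult:
    """Run the full sizing workflow on one frame.

    ``detector`` is either a trained :class:`DetectorModel` or any callable
    mapping an RGB raster to a list of :class:`BoundingBox`.
    """
    t0 = time.perf_counter()
    if not frame.registered:
        if config.depth_intrinsics is None or config.extrinsics is None:
            raise ValueError(
                "unregistered frame needs depth intrinsics and extrinsics"
            )
        frame = register_depth_to_rgb(
            frame, config.depth_intrinsics, config.rgb_intrinsics, config.extrinsics
        )
    if not np.any(frame.depth > 0):
        return FrameResult(frame.frame_id, [], [], skipped="missing-depth")

    rgb = frame.rgb
    depth = frame.depth
    if config.crop_to_depth_fov and config.depth_intrinsics is not None:
        rgb, (x0, y0, x1, y1) = crop_rgb_to_depth_fov(
            rgb, config.rgb_intrinsics, config.depth_intrinsics, config.extrinsics
        )
        depth = depth[y0:y1, x0:x1]
    if config.mirror:
        rgb = mirror_horizontal(rgb)
        depth = mirror_horizontal(depth)
    t_pre = time.perf_counter()

    if isinstance(detector, DetectorModel):
        boxes = detect_fruit(rgb, detector)
    else:
        boxes = list(detector(rgb))
    t_detect = time.perf_counter()

    rows, cols = rgb.shape[:2]
    accepted: list[dict] = []
    rejections: list[tuple[BoundingBox, str]] = []
    for box in boxes:
        ebox = expand_box(box, config.segmentation.box_expand_factor, (cols, rows))
        snip = rgb[ebox.y0 : ebox.y1, ebox.x0 : ebox.x1]
        mask, prov = segment_candidate(snip, config.segmentation)
        if prov.get("otsu_degenerate"):
            rejections.append((box, "otsu-degenerate"))
            continue
        if not mask.any():
            rejections.append((box, "chroma-empty"))
            continue
        labels = _sk_label(mask, connectivity=2)
        box_accepted = []
        first_reason = None
        for lbl in range(1, labels.max() + 1):
            comp = labels == lbl
            try:
                fit = fit_moment_ellipse(comp)
            except ValueError:
                continue
            ok, reason = gate_component(comp, fit, config.gate)
            if ok:
                box_accepted.append((comp, fit))
            elif first_reason is None:
                first_reason = reason
        if not box_accepted:
            rejections.append((box, first_reason or "chroma-empty"))
            continue
        for comp, fit in box_accepted:
            accepted.append(
                {"box": box, "ebox": ebox, "comp": comp, "fit": fit,
                 "area": int(comp.sum())}
            )
    t_seg = time.perf_counter()

    # deduplicate components captured by overlapping (doubled) boxes: keep
    # the larger component when frame-coordinate masks overlap > 50%
    kept: list[dict] = []
    for cand in sorted(accepted, key=lambda c: -c["area"]):
        ys, xs = np.nonzero(cand["comp"])
        pts = set(zip((ys + cand["ebox"].y0).tolist(), (xs + cand["ebox"].x0).tolist()))
        dup = any(
            len(pts & k["pts"]) / min(len(pts), len(k["pts"])) > config.dedupe_overlap
            for k in kept
        )
        if not dup:
            cand["pts"] = pts
            kept.append(cand)
        # a duplicated component is the same fruit seen through another
        # (doubled) detection box; its box still counts as accepted

    measurements: list[FruitMeasurement] = []
    for cand in kept:
        try:
            m = measure_component(
                cand["comp"], depth, config.rgb_intrinsics,
                frame_id=frame.frame_id,
                mask_origin=(cand["ebox"].x0, cand["ebox"].y0),
                ellipse=cand["fit"], config=config.sizing,
            )
        except DepthUnavailableError:
            rejections.append((cand["box"], "depth-missing"))
            continue
        if "depth-near" in m.flags:
            rejections.append((cand["box"], "depth-near"))
            continue
        measurements.append(m)
    t_end = time.perf_counter()

    rejected_ids = {id(b) for b, _ in rejections}
    accepted_boxes: list[BoundingBox] = []
    seen: set[int] = set()
    for cand in accepted:
        b = cand["box"]
        if id(b) not in rejected_ids and id(b) not in seen:
            seen.add(id(b))
            accepted_boxes.append(b)
    return FrameResult(
        frame_id=frame.frame_id,
        measurements=measurements,
        rejections=rejections,
        accepted_boxes=accepted_boxes,
        timings={
            "preprocess_s": t_pre - t0,
            "detect_s": t_detect - t_pre,
            "segment_s": t_seg - t_detect,
            "size_s": t_end - t_seg,
        },
    )


def measurements_to_frame(results: list[FrameResult]) -> pd.DataFrame:
    """Flatten frame results into the measurements table."""
    rows = []
    for res in results:
        for m in res.measurements:
            rows.append(
                {
                    "frame_id": m.frame_id,
                    "x0": m.bbox.x0, "y0": m.bbox.y0,
                    "x1": m.bbox.x1, "y1": m.bbox.y1,
                    "depth_mm": m.depth_mm,
                    "length_mm": m.length_mm,
                    "width_mm": m.width_mm,
                    "epsilon": m.ellipse.eccentricity if m.ellipse else np.nan,
                    "area_ratio": m.ellipse.area_ratio if m.ellipse else np.nan,
                    "flags": ";".join(m.flags),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "frame_id", "x0", "y0", "x1", "y1", "depth_mm",
            "length_mm", "width_mm", "epsilon", "area_ratio", "flags",
        ],
    )


def size_batch(
    frames, config: PipelineConfig, detector
) -> tuple[pd.DataFrame, list[FrameResult]]:
    """Size an iterable of frames; returns the aggregate measurements table
    (ordered by frame_id) and per-frame results."""
    results = []
    for frame in sorted(frames, key=lambda f: f.frame_id):
        results.append(size_frame(frame, config, detector))
    return measurements_to_frame(results), results
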