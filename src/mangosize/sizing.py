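"""Depth lookup at accepted fruit and thin-lens conversion to millimetres.

The minimal bounding box of a gated component supplies the pixel extents.
The vertical (row) extent becomes fruit length through the y-axis focal
length, the horizontal (column) extent becomes width through the x-axis
focal length: fruit hang vertically on their stalks, so the image row axis
tracks the fruit's long axis.  The camera-to-fruit distance D is the mean of
the valid entries of the 2x2 depth block anchored at the bounding-box
centre; fruit nearer than 800 mm are excluded (inside the ToF sensor's
reliable working range).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .camera import CameraIntrinsics, pixels_to_mm
from .detection import BoundingBox
from .ellipse import EllipseFit

__all__ = ["SizingConfig", "FruitMeasurement", "center_depth", "measure_component"]

#: Fruit nearer than this are excluded from sizing (sensor near-field limit).
MIN_DEPTH_MM = 800.0


@dataclass(frozen=True)
class SizingConfig:
    min_depth_mm: float = MIN_DEPTH_MM
    #: constant offset between device front face and the internal sensor
    #: origin, added to measured depth before sizing (0 for synthetic data).
    depth_bias_mm: float = 0.0


@dataclass
class FruitMeasurement:
    """One accepted fruit: pixel box, distance and millimetre dimensions."""

    frame_id: str
    bbox: BoundingBox
    depth_mm: float
    length_mm: float
    width_mm: float
    ellipse: EllipseFit | None = None
    flags: list[str] = field(default_factory=list)


class DepthUnavailableError(ValueError):
    """Raised when the 2x2 depth block holds no valid return."""


def center_depth(
    depth_raster: np.ndarray, center_px: tuple[int, int]
) -> tuple[float, bool]:
    """Mean of the valid entries of the 2x2 block anchored at ``center_px``.

    ``center_px`` is ``(x, y)``; the block is the centre pixel plus its
    right/down neighbours, clipped at the raster edge.  Returns
    ``(D_mm, near_field)`` where ``near_field`` flags D < 800 mm.  Raises
    :class:`DepthUnavailableError` when all block entries are invalid (0).
    """
    depth = np.asarray(depth_raster)
    x, y = int(center_px[0]), int(center_px[1])
    rows, cols = depth.shape
    if not (0 <= x < cols and 0 <= y < rows):
        raise ValueError("centre outside the depth raster")
    block = depth[y : min(y + 2, rows), x : min(x + 2, cols)].astype(float)
    valid = block[block > 0]
    if valid.size == 0:
        raise DepthUnavailableError("no valid depth in the 2x2 block")
    D = float(valid.mean())
    return D, D < MIN_DEPTH_MM


def measure_component(
    component_mask: np.ndarray,
    depth_raster: np.ndarray,
    rgb_intr: CameraIntrinsics,
    *,
    frame_id: str = "",
    mask_origin: tuple[int, int] = (0, 0),
    ellipse: EllipseFit | None = None,
    config: SizingConfig | None = None,
) -> FruitMeasurement:
    """Measure one gate-accepted component in millimetres.

    ``component_mask`` lives in snip coordinates; ``mask_origin`` is the
    snip's (x, y) offset inside the registered frame, so the bounding box and
    the depth lookup are in frame coordinates.  Raises
    :class:`DepthUnavailableError` on missing depth; a near-field fruit
    (D < 800 mm) is returned with the ``depth-near`` flag so callers can
    reject it.
    """
    config = config or SizingConfig()
    mask = np.asarray(component_mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise ValueError("empty component")
    ox, oy = mask_origin
    x0, x1 = int(xs.min()) + ox, int(xs.max()) + 1 + ox
    y0, y1 = int(ys.min()) + oy, int(ys.max()) + 1 + oy
    bbox = BoundingBox(x0, y0, x1, y1)
    cx = (x0 + x1) // 2
    cy = (y0 + y1) // 2
    D, near = center_depth(depth_raster, (cx, cy))
    D += config.depth_bias_mm
    flags: list[str] = []
    if near or D < config.min_depth_mm:
        flags.append("depth-near")
    length = pixels_to_mm(bbox.height, D, rgb_intr.focal_y, rgb_intr.pixel_pitch)
    width = pixels_to_mm(bbox.width, D, rgb_intr.focal_x, rgb_intr.pixel_pitch)
    return FruitMeasurement(
        frame_id=frame_id,
        bbox=bbox,
        depth_mm=D,
        length_mm=length,
        width_mm=width,
        ellipse=ellipse,
        flags=flags,
    )
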