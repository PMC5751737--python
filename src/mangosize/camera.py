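"""Camera models, distortion, depth-to-RGB registration and thin-lens sizing.

The sizing geometry is the classic thin-lens / pinhole relation

    f / D = image_size / real_size

where ``f`` is the lens focal length, ``D`` the camera-to-object plane
distance and image size is (pixel count x pixel pitch) on the sensor.  The
depth camera of the RGB-D unit reports plane-to-plane distance, which is used
directly as ``D`` without ray-length correction.

Conventions
-----------
* Pixel coordinates are 0-based ``(column, row)`` with the origin at the
  top-left; boxes are half-open ``[x0, x1) x [y0, y1)``.
* Depth rasters hold integer millimetres; ``0`` means "no return".
* Focal lengths are in millimetres, pixel pitch in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CameraIntrinsics",
    "Extrinsics",
    "RGBDFrame",
    "KINECT_RGB",
    "KINECT_TOF",
    "undistort_points",
    "distort_points",
    "register_depth_to_rgb",
    "crop_rgb_to_depth_fov",
    "pixels_to_mm",
    "mm_to_pixels",
    "size_error_from_depth_error",
]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole optics of one camera.

    Parameters
    ----------
    resolution : (int, int)
        Sensor resolution as ``(columns, rows)`` in pixels.
    pixel_pitch : float
        Side length of one (square) sensor pixel, micrometres.
    focal_x, focal_y : float
        Effective focal lengths along the sensor x and y axes, millimetres.
    principal_point : (float, float)
        Optical centre ``(px, py)`` in pixel coordinates.
    radial_k1, radial_k2 : float
        Two-coefficient radial distortion model (normalised coordinates).
    """

    resolution: tuple[int, int]
    pixel_pitch: float
    focal_x: float
    focal_y: float
    principal_point: tuple[float, float]
    radial_k1: float = 0.0
    radial_k2: float = 0.0

    def __post_init__(self) -> None:
        if self.focal_x <= 0 or self.focal_y <= 0:
            raise ValueError("focal lengths must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel pitch must be positive")
        px, py = self.principal_point
        cols, rows = self.resolution
        if not (0 <= px < cols and 0 <= py < rows):
            raise ValueError("principal point outside resolution bounds")

    @property
    def pitch_mm(self) -> float:
        """Pixel pitch in millimetres."""
        return self.pixel_pitch * 1e-3

    @property
    def fx_px(self) -> float:
        """Focal length along x expressed in pixels."""
        return self.focal_x / self.pitch_mm

    @property
    def fy_px(self) -> float:
        return self.focal_y / self.pitch_mm

    def with_resolution(self, resolution: tuple[int, int]) -> "CameraIntrinsics":
        """Same optics behind a different (e.g. cropped) raster, principal
        point recentred."""
        cols, rows = resolution
        return replace(
            self, resolution=resolution, principal_point=(cols / 2.0, rows / 2.0)
        )


#: Factory-calibrated optics of the RGB-D unit used throughout the package
#: defaults (1920x1080 colour camera, 3.1 um pitch).
KINECT_RGB = CameraIntrinsics(
    resolution=(1920, 1080),
    pixel_pitch=3.1,
    focal_x=3.2813,
    focal_y=3.5157,
    principal_point=(965.112, 583.268),
    radial_k1=9.3792e-5,
    radial_k2=-7.5342e-8,
)

#: Time-of-flight depth camera of the same unit (512x424, 10 um pitch).
KINECT_TOF = CameraIntrinsics(
    resolution=(512, 424),
    pixel_pitch=10.0,
    focal_x=3.6413,
    focal_y=3.9029,
    principal_point=(263.852, 225.717),
    radial_k1=9.7968e-5,
    radial_k2=-1.9084e-7,
)


@dataclass(frozen=True)
class Extrinsics:
    """Rigid transform from depth-camera to RGB-camera coordinates.

    ``rotation`` is a 3x3 orthonormal matrix with determinant +1,
    ``translation`` a 3-vector in millimetres.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must have determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "Extrinsics":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class RGBDFrame:
    """A paired colour + depth frame.

    ``depth`` is integer millimetres with 0 marking invalid (no ToF return).
    When ``registered`` is True the depth raster is pixel-aligned with the
    (possibly cropped) RGB raster.
    """

    rgb: np.ndarray
    depth: np.ndarray
    registered: bool = False
    frame_id: str = ""
    crop_origin: tuple[int, int] = (0, 0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb raster must be HxWx3")
        if self.depth.ndim != 2:
            raise ValueError("depth raster must be 2D")
        if np.any(self.depth < 0):
            raise ValueError("depth values must be >= 0")
        if self.registered and self.depth.shape != self.rgb.shape[:2]:
            raise ValueError("registered depth must align with the rgb raster")


# ---------------------------------------------------------------------------
# Radial distortion


def _apply_radial(points: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    cx, cy = intr.principal_point
    # normalised coordinates: offset in pixels scaled by focal length in pixels
    xn = (pts[:, 0] - cx) / intr.fx_px
    yn = (pts[:, 1] - cy) / intr.fy_px
    r2 = xn * xn + yn * yn
    scale = 1.0 + intr.radial_k1 * r2 + intr.radial_k2 * r2 * r2
    out = np.empty_like(pts)
    out[:, 0] = cx + xn * scale * intr.fx_px
    out[:, 1] = cy + yn * scale * intr.fy_px
    return out


def undistort_points(points_px, intr: CameraIntrinsics) -> np.ndarray:
    """Apply the two-coefficient radial model about the principal point.

    Points on the principal point, or any point under zero coefficients, map
    to themselves.  The model is invertible within the working field of view
    (see :func:`distort_points`).
    """
    points_px = np.asarray(points_px, dtype=float)
    squeeze = points_px.ndim == 1
    out = _apply_radial(points_px, intr)
    return out[0] if squeeze else out


def distort_points(points_px, intr: CameraIntrinsics, *, iters: int = 8) -> np.ndarray:
    """Numerically invert :func:`undistort_points` by fixed-point iteration."""
    points_px = np.asarray(points_px, dtype=float)
    squeeze = points_px.ndim == 1
    target = np.atleast_2d(points_px)
    guess = target.copy()
    for _ in range(iters):
        guess = guess + (target - _apply_radial(guess, intr))
    return guess[0] if squeeze else guess


# ---------------------------------------------------------------------------
# Registration and cropping


def register_depth_to_rgb(
    frame: RGBDFrame,
    depth_intr: CameraIntrinsics,
    rgb_intr: CameraIntrinsics,
    ext: Extrinsics,
) -> RGBDFrame:
    """Re-sample the depth raster onto the RGB pixel grid.

    Every valid depth pixel is back-projected to a 3D point in depth-camera
    coordinates, moved through the extrinsic transform, and projected with the
    RGB intrinsics.  Where two depth pixels land on the same RGB pixel the
    nearer surface wins (occlusion-correct).  RGB pixels that receive no
    depth sample carry 0.
    """
    if frame.registered:
        raise ValueError("frame is already registered")
    depth = np.asarray(frame.depth)
    rows_d, cols_d = depth.shape
    cols_rgb, rows_rgb = rgb_intr.resolution
    out = np.zeros((rows_rgb, cols_rgb), dtype=depth.dtype)

    v, u = np.nonzero(depth > 0)
    if v.size == 0:
        return RGBDFrame(
            rgb=frame.rgb, depth=out, registered=True, frame_id=frame.frame_id,
            meta={**frame.meta, "registration_empty": True},
        )
    z = depth[v, u].astype(float)
    cx, cy = depth_intr.principal_point
    x = (u - cx) / depth_intr.fx_px * z
    y = (v - cy) / depth_intr.fy_px * z
    pts = np.stack([x, y, z], axis=0)
    moved = ext.rotation @ pts + ext.translation[:, None]
    zr = moved[2]
    ok = zr > 0
    cxr, cyr = rgb_intr.principal_point
    uc = np.round(moved[0, ok] / zr[ok] * rgb_intr.fx_px + cxr).astype(int)
    vc = np.round(moved[1, ok] / zr[ok] * rgb_intr.fy_px + cyr).astype(int)
    zc = np.round(zr[ok]).astype(depth.dtype)
    inb = (uc >= 0) & (uc < cols_rgb) & (vc >= 0) & (vc < rows_rgb)
    uc, vc, zc = uc[inb], vc[inb], zc[inb]
    # nearer surface wins: write in decreasing depth order so the smallest
    # depth lands last
    order = np.argsort(-zc.astype(np.int64), kind="stable")
    out[vc[order], uc[order]] = zc[order]
    return RGBDFrame(
        rgb=frame.rgb, depth=out, registered=True, frame_id=frame.frame_id,
        meta=dict(frame.meta),
    )


def crop_rgb_to_depth_fov(
    rgb_raster: np.ndarray,
    rgb_intr: CameraIntrinsics,
    depth_intr: CameraIntrinsics,
    ext: Extrinsics | None = None,
    *,
    reference_depth: float = 2000.0,
) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Crop the RGB raster to the part covered by the depth field of view.

    The colour camera sees a wider horizontal and narrower vertical field
    than the ToF camera, so side columns without depth coverage are removed.
    Overlap is computed by projecting the depth raster's corner rays (at
    ``reference_depth`` mm when the cameras are offset) into RGB pixel
    coordinates.  Returns the cropped raster and the crop rectangle
    ``(x0, y0, x1, y1)`` (half-open) in original RGB coordinates.
    """
    ext = ext or Extrinsics.identity()
    rows, cols = rgb_raster.shape[:2]
    cols_d, rows_d = depth_intr.resolution
    # Rays through the outer corners/edges of the depth raster.
    border_u = np.array([0.0, cols_d, cols_d, 0.0])
    border_v = np.array([0.0, 0.0, rows_d, rows_d])
    cx, cy = depth_intr.principal_point
    z = reference_depth
    x = (border_u - cx) / depth_intr.fx_px * z
    y = (border_v - cy) / depth_intr.fy_px * z
    pts = np.stack([x, y, np.full(4, z)], axis=0)
    moved = ext.rotation @ pts + ext.translation[:, None]
    cxr, cyr = rgb_intr.principal_point
    u = moved[0] / moved[2] * rgb_intr.fx_px + cxr
    v = moved[1] / moved[2] * rgb_intr.fy_px + cyr
    x0 = max(0, int(np.ceil(u.min())))
    x1 = min(cols, int(np.floor(u.max())))
    y0 = max(0, int(np.ceil(v.min())))
    y1 = min(rows, int(np.floor(v.max())))
    # vertical field: governed by the smaller of the two
    if x1 <= x0 or y1 <= y0:
        raise ValueError("no overlap between RGB and depth fields of view")
    return rgb_raster[y0:y1, x0:x1], (x0, y0, x1, y1)


# ---------------------------------------------------------------------------
# Thin-lens arithmetic


def pixels_to_mm(n_px: float, D: float, focal: float, pitch: float) -> float:
    """Convert a pixel extent to millimetres by the thin-lens relation.

    ``real_size = n_px * pitch * D / focal`` with ``pitch`` in micrometres and
    ``focal`` in millimetres.  One pixel at D = 2000 mm through a 3.5157 mm
    lens with 3.1 um pixels is ~1.76 mm.
    """
    if D <= 0:
        raise ValueError("distance must be positive")
    if focal <= 0:
        raise ValueError("focal length must be positive")
    if n_px < 0:
        raise ValueError("pixel count must be non-negative")
    return n_px * (pitch * 1e-3) * D / focal


def mm_to_pixels(size_mm: float, D: float, focal: float, pitch: float) -> float:
    """Inverse of :func:`pixels_to_mm` (exact round trip)."""
    if D <= 0:
        raise ValueError("distance must be positive")
    return size_mm * focal / (D * pitch * 1e-3)


def size_error_from_depth_error(obj_len: float, D: float, depth_err: float) -> float:
    """First-order size error caused by a depth error.

    The thin-lens estimate is linear in D, so a depth error ``e`` on an
    object of true length L at distance D shifts the size estimate by
    ``L * e / D`` (0.5 mm for a 100 mm object at 2 m with a 10 mm error).
    """
    if D <= 0:
        raise ValueError("distance must be positive")
    return obj_len * depth_err / D
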