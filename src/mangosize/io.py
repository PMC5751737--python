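"""File formats: PNG rasters, camera config files and truth tables.

RGB rasters travel as 8-bit RGB PNG, depth rasters as 16-bit single-channel
PNG holding integer millimetres (0 = no return).  Camera parameters live in
a human-readable JSON file whose keys mirror the calibration sheet
(resolution, sensor size, per-axis focal lengths, principal point, K1/K2).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .camera import CameraIntrinsics, Extrinsics, RGBDFrame
from .detection import BoundingBox
from .synthetic import FruitTruth

__all__ = [
    "read_rgb",
    "write_rgb",
    "read_depth",
    "write_depth",
    "read_camera_config",
    "write_camera_config",
    "load_frame_pairs",
    "write_truth_csv",
    "read_truth_csv",
]


def read_rgb(path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return img[..., :3].astype(np.uint8)


def write_rgb(path, rgb: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(rgb, dtype=np.uint8))


def read_depth(path) -> np.ndarray:
    depth = iio.imread(path)
    if depth.ndim != 2:
        raise ValueError("depth raster must be single-channel")
    return depth.astype(np.int32)


def write_depth(path, depth: np.ndarray) -> None:
    d = np.asarray(depth)
    if np.any(d < 0) or np.any(d > np.iinfo(np.uint16).max):
        raise ValueError("depth out of 16-bit range")
    iio.imwrite(path, d.astype(np.uint16))


def _intr_to_dict(intr: CameraIntrinsics) -> dict:
    return {
        "resolution_px": list(intr.resolution),
        "sensor_size_um": intr.pixel_pitch,
        "focal_length_x_mm": intr.focal_x,
        "focal_length_y_mm": intr.focal_y,
        "principal_point_x_px": intr.principal_point[0],
        "principal_point_y_px": intr.principal_point[1],
        "K1": intr.radial_k1,
        "K2": intr.radial_k2,
    }


def _intr_from_dict(d: dict) -> CameraIntrinsics:
    return CameraIntrinsics(
        resolution=tuple(d["resolution_px"]),
        pixel_pitch=d["sensor_size_um"],
        focal_x=d["focal_length_x_mm"],
        focal_y=d["focal_length_y_mm"],
        principal_point=(d["principal_point_x_px"], d["principal_point_y_px"]),
        radial_k1=d.get("K1", 0.0),
        radial_k2=d.get("K2", 0.0),
    )


def write_camera_config(
    path,
    rgb_intr: CameraIntrinsics,
    depth_intr: CameraIntrinsics | None = None,
    ext: Extrinsics | None = None,
) -> None:
    payload: dict = {"rgb_camera": _intr_to_dict(rgb_intr)}
    if depth_intr is not None:
        payload["depth_camera"] = _intr_to_dict(depth_intr)
    if ext is not None:
        payload["extrinsics"] = {
            "rotation": np.asarray(ext.rotation).tolist(),
            "translation_mm": np.asarray(ext.translation).tolist(),
        }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_camera_config(path) -> tuple[CameraIntrinsics, CameraIntrinsics | None, Extrinsics | None]:
    payload = json.loads(Path(path).read_text())
    rgb = _intr_from_dict(payload["rgb_camera"])
    depth = (
        _intr_from_dict(payload["depth_camera"]) if "depth_camera" in payload else None
    )
    ext = None
    if "extrinsics" in payload:
        e = payload["extrinsics"]
        ext = Extrinsics(np.asarray(e["rotation"]), np.asarray(e["translation_mm"]))
    return rgb, depth, ext


def load_frame_pairs(rgb_dir, depth_dir, *, registered: bool = True):
    """Pair RGB/depth PNGs by filename stem; unpaired files are reported,
    not fatal.  Returns (frames, unpaired_stems)."""
    rgb_dir, depth_dir = Path(rgb_dir), Path(depth_dir)
    rgb_files = {p.stem: p for p in sorted(rgb_dir.glob("*.png"))}
    depth_files = {p.stem: p for p in sorted(depth_dir.glob("*.png"))}
    frames = []
    unpaired = sorted(set(rgb_files) ^ set(depth_files))
    for stem in sorted(set(rgb_files) & set(depth_files)):
        frames.append(
            RGBDFrame(
                rgb=read_rgb(rgb_files[stem]),
                depth=read_depth(depth_files[stem]),
                registered=registered,
                frame_id=stem,
            )
        )
    return frames, unpaired


def write_truth_csv(path, truths_by_frame: dict) -> None:
    rows = []
    for frame_id, truths in truths_by_frame.items():
        for t in truths:
            rows.append(
                {
                    "frame_id": frame_id, "fruit_id": t.fruit_id,
                    "x0": t.bbox.x0, "y0": t.bbox.y0, "x1": t.bbox.x1, "y1": t.bbox.y1,
                    "length_mm": t.length_mm, "width_mm": t.width_mm,
                    "distance_mm": t.distance_mm,
                    "un_occluded": int(t.un_occluded),
                    "occlusion_fraction": t.occlusion_fraction,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_truth_csv(path) -> dict:
    df = pd.read_csv(path)
    out: dict = {}
    for _, row in df.iterrows():
        t = FruitTruth(
            fruit_id=int(row["fruit_id"]),
            bbox=BoundingBox(int(row["x0"]), int(row["y0"]), int(row["x1"]), int(row["y1"])),
            length_mm=float(row["length_mm"]),
            width_mm=float(row["width_mm"]),
            distance_mm=float(row["distance_mm"]),
            un_occluded=bool(row["un_occluded"]),
            occlusion_fraction=float(row.get("occlusion_fraction", 0.0)),
        )
        out.setdefault(str(row["frame_id"]), []).append(t)
    return out
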