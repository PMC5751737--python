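"""Moment-based ellipse fitting and the completeness gate.

A whole mango images as an approximately elliptical blob.  Each connected
component surviving segmentation is summarised by the ellipse with the same
first and second image moments, and four criteria decide whether the
component is a complete, un-occluded fruit:

1. area ``A`` between 1000 and 8000 px (inclusive) — smaller patches are
   background or fragments, larger ones fruit clusters, at ~2 m range;
2. area ratio ``r = 4A / (pi a b) > 0.97`` — a whole fruit fills its fitted
   ellipse, occluded fruit and leafy shapes do not;
3. eccentricity ``eps <= 0.75`` — mango outlines are near-circular, leaves
   and clusters elongate;
4. the component's axis-aligned bounding-box long side must not exceed the
   ellipse major axis by 4 px or more — a thick residual stalk end inflates
   the box but not the fitted ellipse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EllipseFit", "GateConfig", "fit_moment_ellipse", "area_ratio", "gate_component"]


@dataclass(frozen=True)
class EllipseFit:
    """Moment ellipse of one connected component.

    ``major``/``minor`` are full axis lengths in pixels; ``orientation`` is
    the major-axis angle in radians measured from the +x (column) axis,
    counter-clockwise in image convention.
    """

    area: float
    centroid: tuple[float, float]  # (x, y)
    major: float
    minor: float
    orientation: float
    eccentricity: float
    area_ratio: float


@dataclass(frozen=True)
class GateConfig:
    """Completeness-gate constants (pixel units at ~2 m working distance)."""

    area_min: float = 1000.0
    area_max: float = 8000.0
    r_min: float = 0.97
    ecc_max: float = 0.75
    bbox_major_slack: float = 4.0

    def __post_init__(self) -> None:
        if not self.area_min < self.area_max:
            raise ValueError("area_min must be < area_max")
        if not 0 < self.r_min <= 1:
            raise ValueError("r_min must be in (0, 1]")
        if not 0 < self.ecc_max < 1:
            raise ValueError("ecc_max must be in (0, 1)")


def fit_moment_ellipse(component_mask: np.ndarray) -> EllipseFit:
    """Fit the ellipse sharing the component's first and second moments.

    The second central moment matrix of a solid ellipse with full axes
    ``a >= b`` has eigenvalues ``(a/4)^2`` and ``(b/4)^2``, so the axes are
    four times the square roots of the mask's covariance eigenvalues.
    """
    mask = np.asarray(component_mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    n = xs.size
    if n < 5:
        raise ValueError("component too small for a moment ellipse (need >= 5 px)")
    cx, cy = xs.mean(), ys.mean()
    dx, dy = xs - cx, ys - cy
    mxx = np.mean(dx * dx)
    myy = np.mean(dy * dy)
    mxy = np.mean(dx * dy)
    cov = np.array([[mxx, mxy], [mxy, myy]])
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0:
        raise ValueError("degenerate component: zero second moment")
    minor = 4.0 * np.sqrt(evals[0])
    major = 4.0 * np.sqrt(evals[1])
    vx, vy = evecs[:, 1]
    orientation = float(np.arctan2(vy, vx)) % np.pi
    ecc = float(np.sqrt(max(0.0, 1.0 - (minor / major) ** 2)))
    r = area_ratio(float(n), major, minor)
    return EllipseFit(
        area=float(n),
        centroid=(float(cx), float(cy)),
        major=float(major),
        minor=float(minor),
        orientation=orientation,
        eccentricity=ecc,
        area_ratio=r,
    )


def area_ratio(A: float, a: float, b: float) -> float:
    """Ratio of component area to fitted-ellipse area: r = 4A / (pi a b)."""
    if a <= 0 or b <= 0:
        raise ValueError("axis lengths must be positive")
    return 4.0 * A / (np.pi * a * b)


def gate_component(
    component_mask: np.ndarray, fit: EllipseFit, config: GateConfig | None = None
) -> tuple[bool, str]:
    """Apply the four completeness criteria; report the first failure.

    Returns ``(accepted, reason)`` with reason ``"ok"`` on acceptance or one
    of ``area-low``, ``area-high``, ``ratio-low``, ``ecc-high``,
    ``bbox-major``.
    """
    config = config or GateConfig()
    if fit.area < config.area_min:
        return False, "area-low"
    if fit.area > config.area_max:
        return False, "area-high"
    if not fit.area_ratio > config.r_min:
        return False, "ratio-low"
    if fit.eccentricity > config.ecc_max:
        return False, "ecc-high"
    ys, xs = np.nonzero(np.asarray(component_mask, dtype=bool))
    long_side = max(xs.max() - xs.min() + 1, ys.max() - ys.min() + 1)
    if long_side - fit.major >= config.bbox_major_slack:
        return False, "bbox-major"
    return True, "ok"
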