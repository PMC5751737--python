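"""Allometric mass estimation, width-matching evaluation rule and sampling.

Mango mass (g) scales with the product of the lineal dimensions (cm):
``M = k L W T`` with k ~ 0.49-0.51, simplified to ``M = k L ((W+T)/2)^2``
when only an average cross-section is available, or ``M = 0.42 L W^2`` when
thickness is unmeasured.  Because a camera views fruit on the tree at an
uncontrolled orientation, the imaged width lies between the true width W and
thickness T; machine-vision width is therefore evaluated against whichever
of the two caliper values it is closer to.

The pipeline's internal lineal unit is the millimetre; these functions
convert to centimetres at the boundary since the mass relations are stated
in cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "FruitDims",
    "mass_lwt",
    "mass_lw_avg",
    "mass_lw2",
    "width_reference",
    "sample_size",
]


@dataclass(frozen=True)
class FruitDims:
    """Lineal dimensions in centimetres: length L, width W, thickness T."""

    L: float
    W: float
    T: float | None = None

    def __post_init__(self) -> None:
        if self.L < 0 or self.W < 0 or (self.T is not None and self.T < 0):
            raise ValueError("dimensions must be non-negative")


def mass_lwt(dims: FruitDims, k: float = 0.5) -> float:
    """Mass (g) from M = k L W T, dimensions in cm."""
    if dims.T is None:
        raise ValueError("thickness required; use mass_lw_avg or mass_lw2")
    return k * dims.L * dims.W * dims.T


def mass_lw_avg(dims: FruitDims, k: float = 0.5) -> float:
    """Mass (g) from M = k L ((W + T) / 2)^2, dimensions in cm."""
    if dims.T is None:
        raise ValueError("thickness required; use mass_lw2")
    return k * dims.L * ((dims.W + dims.T) / 2.0) ** 2


def mass_lw2(L_cm: float, W_cm: float) -> float:
    """Mass (g) from M = 0.42 L W^2, the two-dimension relation (cm in)."""
    if L_cm < 0 or W_cm < 0:
        raise ValueError("dimensions must be non-negative")
    return 0.42 * L_cm * W_cm * W_cm


def width_reference(W_manual: float, T_manual: float, width_mv: float) -> float:
    """Caliper reference for a machine-vision width: the closer of W and T.

    Fruit orientation on the tree is uncontrolled, so the imaged width can
    correspond to anything between the caliper width and thickness.  Ties go
    to W.
    """
    if W_manual <= 0 or T_manual <= 0 or width_mv <= 0:
        raise ValueError("dimensions must be positive")
    if abs(width_mv - W_manual) <= abs(width_mv - T_manual):
        return W_manual
    return T_manual


def sample_size(SD: float, e: float, *, t_stat: float = 1.96, ceil: bool = False) -> int:
    """Fruit count needed to estimate mean size to error ``e``: (t SD / e)^2.

    ``SD`` is the population standard deviation and ``e`` the accepted error
    (both in the same units, e.g. mm); 1.96 is the t statistic at 95%
    confidence.  Rounds to the nearest fruit by default; ``ceil=True`` gives
    the conservative count.
    """
    if SD <= 0:
        raise ValueError("SD must be positive")
    if e <= 0:
        raise ValueError("accepted error must be positive")
    n = (t_stat * SD / e) ** 2
    return math.ceil(n) if ceil else round(n)
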