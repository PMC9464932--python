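"""HU ↔ relative electron density conversion and per-structure ED statistics.

Bulk density assignment replaces every voxel of a contoured structure with
the structure's mean relative electron density (relative ED, water = 1).
This module supplies the calibration curve that converts CT numbers to
relative ED, its inverse (used to store a synthetic CT back as HU), and the
masked statistics that both the syCT builder and the troubleshooting
heuristics rely on.

The calibration is piecewise linear between user-supplied anchor points and
clamps outside the anchored range. Scanner curves vary; the default here is
a generic curve with the physically fixed air (−1000 HU → 0.0) and water
(0 HU → 1.0) anchors, and is fully overridable from the QA config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .grid import VoxelGrid

__all__ = [
    "EDCalibration",
    "EDAssignment",
    "DEFAULT_CALIBRATION",
    "hu_to_ed",
    "ed_to_hu",
    "mean_ed",
    "ed_stats",
]


@dataclass(frozen=True)
class EDCalibration:
    """Piecewise-linear HU → relative ED calibration curve.

    ``anchor_points`` is an ordered list of ``(HU, ED)`` pairs with strictly
    increasing HU and non-decreasing ED; it must contain the air anchor
    (≈ −1000 HU, ED 0) and the water anchor (0 HU, ED 1).
    """

    anchor_points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        pts = tuple((float(h), float(e)) for h, e in self.anchor_points)
        object.__setattr__(self, "anchor_points", pts)
        hu = self.hu
        ed = self.ed
        if len(pts) < 2:
            raise ValueError("calibration needs at least two anchor points")
        if not np.all(np.diff(hu) > 0):
            raise ValueError("anchor HU values must be strictly increasing")
        if not np.all(np.diff(ed) >= 0):
            raise ValueError("anchor ED values must be non-decreasing")
        if not np.any((np.abs(hu + 1000) <= 100) & (ed == 0.0)):
            raise ValueError("calibration must contain an air anchor (≈ −1000 HU → ED 0.0)")
        if not np.any((hu == 0.0) & (ed == 1.0)):
            raise ValueError("calibration must contain the water anchor (0 HU → ED 1.0)")

    @property
    def hu(self) -> np.ndarray:
        return np.array([p[0] for p in self.anchor_points])

    @property
    def ed(self) -> np.ndarray:
        return np.array([p[1] for p in self.anchor_points])

    @property
    def invertible(self) -> bool:
        """True when ED is strictly increasing, so ED → HU is well defined."""
        return bool(np.all(np.diff(self.ed) > 0))


#: Generic CT-to-relative-ED curve (air, lung, water, soft tissue, bone).
DEFAULT_CALIBRATION = EDCalibration(
    anchor_points=(
        (-1000.0, 0.00),
        (-200.0, 0.80),
        (0.0, 1.00),
        (100.0, 1.07),
        (1000.0, 1.60),
        (3000.0, 2.30),
    )
)


def hu_to_ed(hu, calibration: EDCalibration = DEFAULT_CALIBRATION):
    """Convert HU (scalar, array or :class:`VoxelGrid`) to relative ED.

    Piecewise-linear interpolation between the calibration anchors, clamped
    to the end anchors outside the anchored HU range.
    """
    if isinstance(hu, VoxelGrid):
        return hu.with_values(hu_to_ed(hu.values, calibration))
    return np.interp(hu, calibration.hu, calibration.ed)


def ed_to_hu(ed, calibration: EDCalibration = DEFAULT_CALIBRATION):
    """Invert the calibration: relative ED to HU, clamped at the end anchors.

    Raises ``ValueError`` when the calibration is not strictly monotone in
    ED (the inverse would be ill-defined).
    """
    if isinstance(ed, VoxelGrid):
        return ed.with_values(ed_to_hu(ed.values, calibration))
    if not calibration.invertible:
        raise ValueError("calibration ED values are not strictly increasing; cannot invert")
    return np.interp(ed, calibration.ed, calibration.hu)


@dataclass
class EDAssignment:
    """One row of the bulk-assignment table of a reference plan.

    ``mean_ed`` may be ``None``, in which case the builder computes it from
    the reference CT over the structure's rasterized mask. Priorities must
    be unique across one table; at overlaps the higher priority wins.
    """

    structure_name: str
    priority: int
    mean_ed: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mean_ed is not None and self.mean_ed < 0:
            raise ValueError(f"mean_ed must be non-negative, got {self.mean_ed}")


def _masked_ed(ct: VoxelGrid, mask: np.ndarray, calibration: EDCalibration) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != ct.shape:
        raise ValueError("mask shape does not match CT grid")
    if not mask.any():
        raise ValueError("empty structure: mask selects no voxels")
    return hu_to_ed(np.asarray(ct.values, dtype=float)[mask], calibration)


def mean_ed(
    ct: VoxelGrid, mask: np.ndarray, calibration: EDCalibration = DEFAULT_CALIBRATION
) -> float:
    """Arithmetic mean relative ED over the masked voxels of a CT."""
    return float(_masked_ed(ct, mask, calibration).mean())


def ed_stats(
    ct: VoxelGrid, mask: np.ndarray, calibration: EDCalibration = DEFAULT_CALIBRATION
) -> dict[str, float]:
    """Mean, population standard deviation, min and max of ED within a mask.

    The standard deviation is the homogeneity statistic the troubleshooting
    step uses to flag structures (e.g. lung targets) whose internal density
    spread makes a single bulk ED a poor approximation.
    """
    ed = _masked_ed(ct, mask, calibration)
    return {
        "mean": float(ed.mean()),
        "std": float(ed.std()),  # population std: a mask is the full voxel population
        "min": float(ed.min()),
        "max": float(ed.max()),
    }
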