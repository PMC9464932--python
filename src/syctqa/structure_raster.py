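"""Planar contours → voxel masks, and priority resolution of overlaps.

Bulk density assignment is defined on voxel sets: each contoured structure
becomes a boolean mask on the CT grid (a voxel belongs to the structure iff
its center lies inside the slice's polygon(s) under the even–odd rule), and
where structures overlap, the one with the higher priority claims the voxel.

The voxel-center rule keeps masks boolean — bulk assignment is binary per
voxel, so partial-volume weighting would buy nothing. Multiple polygons on
one slice combine by even–odd parity, which is how structure sets encode
holes (e.g. a skull annulus as outer + inner contour).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as MplPath

from .dicom_io import ContourStructure
from .grid import VoxelGrid

logger = logging.getLogger(__name__)

__all__ = ["StructureMask", "PriorityLabelMap", "rasterize", "resolve_priorities"]

#: points within this distance (mm) of a polygon edge count as inside.
EDGE_TOL = 1e-9


@dataclass
class StructureMask:
    """Boolean voxel mask of one structure on a reference grid."""

    name: str
    mask: np.ndarray  # bool, congruent with the reference grid
    voxel_volume: float  # cc
    priority: int = 0

    @property
    def volume_cc(self) -> float:
        return float(self.mask.sum()) * self.voxel_volume

    def with_priority(self, priority: int) -> "StructureMask":
        return StructureMask(self.name, self.mask, self.voxel_volume, priority)


@dataclass
class PriorityLabelMap:
    """Integer label per voxel naming the winning structure (0 = none).

    Labels are canonical: structures sorted by ascending priority get labels
    1..n, so the map is independent of the order masks were supplied in.
    """

    labels: np.ndarray  # int, congruent with the reference grid
    legend: dict[int, str]  # label -> structure name
    priorities: dict[int, int]  # label -> priority

    def label_of(self, name: str) -> int:
        for lab, n in self.legend.items():
            if n == name:
                return lab
        raise KeyError(f"no structure named '{name}' in label map")


def _fill_slice(
    polys: list[np.ndarray], xc: np.ndarray, yc: np.ndarray
) -> np.ndarray:
    """Even–odd fill of one slice's polygons at the given voxel centers.

    ``xc``/``yc`` are the 1D center coordinates; returns an (ny, nx) bool
    array. Each polygon toggles parity (XOR), so nested contours carve
    holes. Points within ``EDGE_TOL`` of an edge count as inside.
    """
    xx, yy = np.meshgrid(xc, yc)  # (ny, nx)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    inside = np.zeros(pts.shape[0], dtype=bool)
    for poly in polys:
        # Path(closed=True) treats the final vertex as the closure point, so
        # the first vertex must be repeated explicitly
        ring = np.vstack([poly[:, :2], poly[:1, :2]])
        path = MplPath(ring, closed=True)
        # contains_points' radius expands/shrinks with polygon winding sense;
        # query both signs so edge points are inside regardless of sense.
        hit = path.contains_points(pts, radius=EDGE_TOL) | path.contains_points(
            pts, radius=-EDGE_TOL
        )
        inside ^= hit
    return inside.reshape(len(yc), len(xc))


def rasterize(structure: ContourStructure, grid: VoxelGrid) -> StructureMask:
    """Rasterize a planar-contour structure onto a grid as a boolean mask.

    Contours are assigned to the nearest slice plane (they must lie within
    half a slice spacing of it); a voxel is inside iff its center is inside
    the polygons of its slice under the even–odd rule. Polygons with fewer
    than 3 vertices are skipped with a warning; a structure whose planes all
    miss the grid yields an empty mask with a warning.
    """
    zc, yc, xc = grid.axis_coords()
    dz = grid.spacing[2]
    by_slice: dict[int, list[np.ndarray]] = {}
    n_used = 0
    for poly in structure.contours:
        if poly.shape[0] < 3:
            logger.warning(
                "structure '%s': skipping degenerate polygon with %d vertices",
                structure.name,
                poly.shape[0],
            )
            continue
        z = float(poly[:, 2].mean())
        k = int(round((z - zc[0]) / dz))
        if k < 0 or k >= len(zc) or abs(z - zc[min(max(k, 0), len(zc) - 1)]) > dz / 2 + 1e-9:
            continue  # plane outside the grid
        by_slice.setdefault(k, []).append(poly)
        n_used += 1

    mask = np.zeros(grid.shape, dtype=bool)
    if n_used == 0:
        logger.warning("structure '%s' has no contours on the grid; empty mask", structure.name)
        return StructureMask(structure.name, mask, grid.voxel_volume_cc)
    for k, polys in by_slice.items():
        mask[k] = _fill_slice(polys, xc, yc)
    return StructureMask(structure.name, mask, grid.voxel_volume_cc)


def resolve_priorities(
    masks: list[StructureMask], *, higher_wins: bool = True
) -> PriorityLabelMap:
    """Resolve overlapping masks into a per-voxel winning-structure label map.

    At each voxel covered by several structures the one with the highest
    priority wins (set ``higher_wins=False`` for systems that rank 1 as
    highest). Priorities must be unique; duplicates raise before any
    computation. The result is independent of the order of ``masks``.
    """
    if not masks:
        raise ValueError("no masks given")
    prios = [m.priority for m in masks]
    if len(set(prios)) != len(prios):
        dupes = sorted({p for p in prios if prios.count(p) > 1})
        raise ValueError(f"duplicate priorities {dupes}; priorities must be unique")

    # canonical label order: ascending effective priority -> labels 1..n,
    # so later (higher-priority) structures overwrite earlier ones.
    key = (lambda m: m.priority) if higher_wins else (lambda m: -m.priority)
    ordered = sorted(masks, key=key)
    labels = np.zeros(ordered[0].mask.shape, dtype=np.int32)
    legend: dict[int, str] = {}
    priorities: dict[int, int] = {}
    for lab, m in enumerate(ordered, start=1):
        if m.mask.shape != labels.shape:
            raise ValueError(f"mask '{m.name}' geometry differs from the others")
        labels[m.mask] = lab
        legend[lab] = m.name
        priorities[lab] = m.priority
    return PriorityLabelMap(labels=labels, legend=legend, priorities=priorities)
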