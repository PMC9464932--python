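"""Voxel-grid geometry model shared by every stage of the QA pipeline.

All grids live in the DICOM patient coordinate system. Conventions used
throughout the package:

* array axis order is ``(z, y, x)`` (slice, row, column), the natural order
  of an assembled axial CT series;
* ``spacing`` and ``origin`` are stored in ``(x, y, z)`` order, the order
  DICOM and SimpleITK use;
* ``origin`` is the patient-coordinate position (mm) of the *center* of
  voxel ``[0, 0, 0]``, so the voxel ``[k, j, i]`` sits at
  ``origin + (i*dx, j*dy, k*dz)``;
* only axial orientations (row cosine ``(1,0,0)``, column cosine
  ``(0,1,0)``) are supported — non-axial data is rejected at the DICOM
  boundary.

The same container carries HU, relative electron density, dose in Gy, or a
dimensionless gamma field; the unit is contextual, not encoded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = ["VoxelGrid", "AXIAL_ORIENTATION"]

#: row/column direction cosines of an axial slice, DICOM style.
AXIAL_ORIENTATION: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)

_ORTHO_TOL = 1e-6


@dataclass
class VoxelGrid:
    """A rectilinear 3D scalar field with patient-coordinate geometry.

    Parameters
    ----------
    values
        Scalar array of shape ``(nz, ny, nx)``.
    spacing
        Voxel spacing ``(dx, dy, dz)`` in mm; strictly positive.
    origin
        Patient coordinate ``(x, y, z)`` in mm of the first voxel center.
    orientation
        Six direction cosines (row then column vector). Axial only.
    frame_of_reference
        Opaque DICOM frame-of-reference identifier ('' when unknown).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: tuple[float, ...] = AXIAL_ORIENTATION
    frame_of_reference: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.orientation = tuple(float(c) for c in self.orientation)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self._check_orientation()

    def _check_orientation(self) -> None:
        row = np.array(self.orientation[:3])
        col = np.array(self.orientation[3:])
        if (
            abs(np.linalg.norm(row) - 1) > _ORTHO_TOL
            or abs(np.linalg.norm(col) - 1) > _ORTHO_TOL
            or abs(row @ col) > _ORTHO_TOL
        ):
            raise ValueError("orientation vectors are not orthonormal")
        if np.abs(np.array(self.orientation) - np.array(AXIAL_ORIENTATION)).max() > _ORTHO_TOL:
            raise ValueError(
                "only axial orientation is supported; got direction cosines "
                f"{self.orientation}"
            )

    # -- derived geometry ------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # (nz, ny, nx)

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cubic centimetres."""
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Patient coordinates of voxel centers along each array axis.

        Returns ``(z, y, x)`` 1D arrays matching the array axis order.
        """
        nz, ny, nx = self.shape
        x0, y0, z0 = self.origin
        dx, dy, dz = self.spacing
        return (
            z0 + dz * np.arange(nz),
            y0 + dy * np.arange(ny),
            x0 + dx * np.arange(nx),
        )

    def world_to_index(self, points_xyz: np.ndarray) -> np.ndarray:
        """Map patient-coordinate points (n, 3) in (x, y, z) mm to fractional
        array indices (n, 3) in (k, j, i) order."""
        p = np.atleast_2d(np.asarray(points_xyz, dtype=float))
        x0, y0, z0 = self.origin
        dx, dy, dz = self.spacing
        out = np.empty_like(p)
        out[:, 0] = (p[:, 2] - z0) / dz
        out[:, 1] = (p[:, 1] - y0) / dy
        out[:, 2] = (p[:, 0] - x0) / dx
        return out

    # -- relations -------------------------------------------------------

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        """True when shape, spacing, origin and orientation all agree."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.orientation, other.orientation, atol=tol)
        )

    def with_values(self, values: np.ndarray) -> "VoxelGrid":
        """A grid with identical geometry but different voxel values."""
        if np.shape(values) != self.shape:
            raise ValueError("values shape does not match grid shape")
        return replace(self, values=np.asarray(values))

    def resample_to(self, target: "VoxelGrid", fill: float = 0.0) -> "VoxelGrid":
        """Trilinearly resample this field onto ``target``'s geometry.

        Sample points outside this grid's voxel-center hull receive
        ``fill`` (dose grids smaller than the CT are padded with zero dose).
        """
        if self.same_geometry(target):
            return target.with_values(self.values.copy())
        zt, yt, xt = target.axis_coords()
        zz, yy, xx = np.meshgrid(zt, yt, xt, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        idx = self.world_to_index(pts)
        inside = np.all((idx >= 0) & (idx <= np.array(self.shape) - 1), axis=1)
        sampled = ndimage.map_coordinates(
            np.asarray(self.values, dtype=float), idx.T, order=1, mode="nearest"
        )
        sampled[~inside] = fill
        return target.with_values(sampled.reshape(target.shape))
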