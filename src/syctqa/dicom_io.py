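"""DICOM-RT input/output.

Reads and writes the three DICOM objects the QA workflow touches — a CT
image series, an RT structure set and RT dose grids — and converts them to
and from the internal :class:`~syctqa.grid.VoxelGrid` / contour model.
Only axial series are supported; geometry follows the DICOM convention
(patient coordinates in mm, origin at the center of the first voxel).

Synthetic CTs are voxel fields of relative electron density; to persist one
as a CT series, :func:`write_syct` maps ED back to HU through the inverse of
the (strictly monotone) calibration curve and stores the result like any
other CT series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .ed_model import DEFAULT_CALIBRATION, EDCalibration, ed_to_hu
from .grid import AXIAL_ORIENTATION, VoxelGrid

logger = logging.getLogger(__name__)

__all__ = [
    "ContourStructure",
    "read_ct_series",
    "write_ct_series",
    "read_rtstruct",
    "write_rtstruct",
    "read_rtdose",
    "write_rtdose",
    "write_syct",
    "save_nrrd",
]

_SLICE_TOL = 1e-3  # mm tolerance on inter-slice gap uniformity
_CT_STORAGE = "1.2.840.10008.5.1.4.1.1.2"
_RTDOSE_STORAGE = "1.2.840.10008.5.1.4.1.1.481.2"
_RTSTRUCT_STORAGE = "1.2.840.10008.5.1.4.1.1.481.3"


@dataclass
class ContourStructure:
    """A named structure as a set of closed planar polygons.

    Each contour is an ``(n, 3)`` array of patient-coordinate vertices in
    mm, all on one axial plane; polygons on the same slice combine by
    even–odd parity when rasterized (holes supported).
    """

    name: str
    contours: list[np.ndarray] = field(default_factory=list)
    color: Optional[tuple[int, int, int]] = None

    def __post_init__(self) -> None:
        clean = []
        for poly in self.contours:
            arr = np.asarray(poly, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"contour of '{self.name}' is not an (n, 3) vertex array")
            if arr.shape[0] >= 3 and np.ptp(arr[:, 2]) > 1e-3:
                raise ValueError(
                    f"contour of '{self.name}' is not planar: z spread {np.ptp(arr[:, 2]):.4g} mm"
                )
            clean.append(arr)
        self.contours = clean


# ---------------------------------------------------------------------------
# CT series
# ---------------------------------------------------------------------------

def read_ct_series(directory) -> VoxelGrid:
    """Assemble an axial CT series from a directory into a HU voxel grid.

    Slices are sorted by patient z; the rescale slope/intercept of each
    slice is applied so the returned values are Hounsfield units.

    Raises
    ------
    ValueError
        ``"mixed series"`` when files belong to more than one series, or
        ``"irregular slice spacing"`` when inter-slice gaps differ by more
        than 1e-3 mm (e.g. a missing slice).
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise FileNotFoundError(f"no .dcm files in {directory}")
    slices = [pydicom.dcmread(f) for f in files]
    series_uids = {ds.SeriesInstanceUID for ds in slices}
    if len(series_uids) > 1:
        raise ValueError(f"mixed series in {directory}: {sorted(series_uids)}")
    frames = {getattr(ds, "FrameOfReferenceUID", "") for ds in slices}
    if len(frames) > 1:
        raise ValueError(f"mixed series: multiple frames of reference {sorted(frames)}")

    for ds in slices:
        _require_axial(ds.ImageOrientationPatient)
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    z = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    if len(z) > 1:
        gaps = np.diff(z)
        if np.ptp(gaps) > _SLICE_TOL:
            raise ValueError(
                f"irregular slice spacing: gaps range {gaps.min():.4f}–{gaps.max():.4f} mm"
            )
        dz = float(gaps.mean())
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0) or 1.0)

    first = slices[0]
    dy, dx = (float(v) for v in first.PixelSpacing)  # row spacing, column spacing
    hu = np.stack(
        [
            ds.pixel_array.astype(np.float64) * float(getattr(ds, "RescaleSlope", 1.0))
            + float(getattr(ds, "RescaleIntercept", 0.0))
            for ds in slices
        ]
    )
    origin = (
        float(first.ImagePositionPatient[0]),
        float(first.ImagePositionPatient[1]),
        float(z[0]),
    )
    return VoxelGrid(
        values=hu,
        spacing=(dx, dy, dz),
        origin=origin,
        orientation=AXIAL_ORIENTATION,
        frame_of_reference=getattr(first, "FrameOfReferenceUID", ""),
    )


def _require_axial(iop) -> None:
    cos = np.array([float(v) for v in iop])
    if np.abs(cos - np.array(AXIAL_ORIENTATION)).max() > 1e-4:
        raise ValueError(f"only axial orientation is supported, got {list(cos)}")


def _file_meta(storage_uid: str, instance_uid: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = storage_uid
    meta.MediaStorageSOPInstanceUID = instance_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def _common_ids(grid: VoxelGrid) -> tuple[str, str]:
    frame = grid.frame_of_reference or generate_uid()
    return frame, generate_uid()


def write_ct_series(grid: VoxelGrid, directory, *, series_description: str = "CT") -> list[Path]:
    """Write a HU grid as an axial CT series (one int16 file per slice).

    HU values are rounded to the nearest integer and stored with rescale
    slope 1 / intercept −1024, so a round trip is exact for integer HU and
    within 0.5 HU otherwise. Returns the written file paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frame, series_uid = _common_ids(grid)
    study_uid = generate_uid()
    nz, ny, nx = grid.shape
    dx, dy, dz = grid.spacing
    x0, y0, z0 = grid.origin
    stored = np.round(np.asarray(grid.values, dtype=np.float64)).astype(np.int64) + 1024
    stored = np.clip(stored, -32768, 32767).astype(np.int16)

    paths = []
    for k in range(nz):
        sop_uid = generate_uid()
        ds = Dataset()
        ds.file_meta = _file_meta(_CT_STORAGE, sop_uid)
        ds.SOPClassUID = _CT_STORAGE
        ds.SOPInstanceUID = sop_uid
        ds.Modality = "CT"
        ds.SeriesDescription = series_description
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [x0, y0, z0 + k * dz]
        ds.ImageOrientationPatient = list(AXIAL_ORIENTATION)
        ds.PixelSpacing = [dy, dx]
        ds.SliceThickness = dz
        ds.Rows, ds.Columns = ny, nx
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.PixelData = stored[k].tobytes()
        path = directory / f"ct_{k:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# RT structure set
# ---------------------------------------------------------------------------

def read_rtstruct(file, reference_grid: VoxelGrid) -> list[ContourStructure]:
    """Read an RTSTRUCT into a list of contour structures.

    The structure set's referenced frame of reference must match the
    reference grid's; vertex coordinates are preserved in mm. A ROI with no
    contour items yields a structure with an empty contour list (warning).
    """
    ds = pydicom.dcmread(file)
    frame = ""
    for ref in getattr(ds, "ReferencedFrameOfReferenceSequence", []):
        frame = getattr(ref, "FrameOfReferenceUID", "")
        break
    if reference_grid.frame_of_reference and frame and frame != reference_grid.frame_of_reference:
        raise ValueError(
            "frame of reference mismatch: RTSTRUCT references "
            f"'{frame}' but the grid is '{reference_grid.frame_of_reference}'"
        )
    names = {int(roi.ROINumber): str(roi.ROIName) for roi in ds.StructureSetROISequence}
    contours_by_roi: dict[int, list[np.ndarray]] = {n: [] for n in names}
    for rc in getattr(ds, "ROIContourSequence", []):
        num = int(rc.ReferencedROINumber)
        for item in getattr(rc, "ContourSequence", []):
            data = np.array(item.ContourData, dtype=float).reshape(-1, 3)
            contours_by_roi.setdefault(num, []).append(data)

    out = []
    for num, name in names.items():
        polys = contours_by_roi.get(num, [])
        if not polys:
            logger.warning("ROI '%s' has no contour items", name)
        out.append(ContourStructure(name=name, contours=polys))
    return out


def write_rtstruct(structures: Sequence[ContourStructure], file, reference_grid: VoxelGrid) -> Path:
    """Write contour structures as a minimal RTSTRUCT referencing the grid."""
    file = Path(file)
    file.parent.mkdir(parents=True, exist_ok=True)
    sop_uid = generate_uid()
    ds = Dataset()
    ds.file_meta = _file_meta(_RTSTRUCT_STORAGE, sop_uid)
    ds.SOPClassUID = _RTSTRUCT_STORAGE
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTSTRUCT"
    ds.StructureSetLabel = "syctqa"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()

    ref = Dataset()
    ref.FrameOfReferenceUID = reference_grid.frame_of_reference or generate_uid()
    ds.ReferencedFrameOfReferenceSequence = [ref]

    roi_seq, contour_seq = [], []
    for i, s in enumerate(structures, start=1):
        roi = Dataset()
        roi.ROINumber = i
        roi.ROIName = s.name
        roi.ReferencedFrameOfReferenceUID = ref.FrameOfReferenceUID
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        roi_seq.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = i
        if s.color is not None:
            rc.ROIDisplayColor = list(s.color)
        items = []
        for poly in s.contours:
            item = Dataset()
            item.ContourGeometricType = "CLOSED_PLANAR"
            item.NumberOfContourPoints = poly.shape[0]
            item.ContourData = [float(v) for v in poly.ravel()]
            items.append(item)
        rc.ContourSequence = items
        contour_seq.append(rc)
    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    ds.save_as(file, enforce_file_format=True)
    return file


# ---------------------------------------------------------------------------
# RT dose
# ---------------------------------------------------------------------------

def read_rtdose(file) -> VoxelGrid:
    """Read an RTDOSE grid; stored integers × DoseGridScaling → Gy."""
    ds = pydicom.dcmread(file)
    if "DoseGridScaling" not in ds:
        raise ValueError(f"{file}: RTDOSE has no DoseGridScaling; cannot convert to Gy")
    _require_axial(ds.ImageOrientationPatient)
    scaling = float(ds.DoseGridScaling)
    dose = ds.pixel_array.astype(np.float64) * scaling
    if dose.ndim == 2:
        dose = dose[None]
    offsets = np.array([float(v) for v in ds.GridFrameOffsetVector])
    dz = float(offsets[1] - offsets[0]) if len(offsets) > 1 else 1.0
    dy, dx = (float(v) for v in ds.PixelSpacing)
    origin = (
        float(ds.ImagePositionPatient[0]),
        float(ds.ImagePositionPatient[1]),
        float(ds.ImagePositionPatient[2]) + float(offsets[0]),
    )
    return VoxelGrid(
        values=dose,
        spacing=(dx, dy, dz),
        origin=origin,
        orientation=AXIAL_ORIENTATION,
        frame_of_reference=getattr(ds, "FrameOfReferenceUID", ""),
    )


def write_rtdose(grid: VoxelGrid, file) -> Path:
    """Write a dose grid (Gy) as a multi-frame uint32 RTDOSE file.

    DoseGridScaling is chosen as max dose / (2³² − 1), so the round-trip
    error is at most one scaling unit per voxel.
    """
    file = Path(file)
    file.parent.mkdir(parents=True, exist_ok=True)
    dose = np.asarray(grid.values, dtype=np.float64)
    if dose.min() < 0:
        raise ValueError("dose values must be non-negative")
    scaling = dose.max() / (2**32 - 1) if dose.max() > 0 else 1.0
    stored = np.round(dose / scaling).astype(np.uint32)

    sop_uid = generate_uid()
    nz, ny, nx = grid.shape
    dx, dy, dz = grid.spacing
    ds = Dataset()
    ds.file_meta = _file_meta(_RTDOSE_STORAGE, sop_uid)
    ds.SOPClassUID = _RTDOSE_STORAGE
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTDOSE"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.FrameOfReferenceUID = grid.frame_of_reference or generate_uid()
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    ds.ImagePositionPatient = list(grid.origin)
    ds.ImageOrientationPatient = list(AXIAL_ORIENTATION)
    ds.GridFrameOffsetVector = [k * dz for k in range(nz)]
    ds.PixelSpacing = [dy, dx]
    ds.SliceThickness = dz
    ds.NumberOfFrames = nz
    ds.Rows, ds.Columns = ny, nx
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = stored.tobytes()
    ds.save_as(file, enforce_file_format=True)
    return file


def write_syct(
    ed_grid: VoxelGrid,
    directory,
    calibration: EDCalibration = DEFAULT_CALIBRATION,
) -> list[Path]:
    """Persist a relative-ED synthetic CT as a DICOM CT series.

    ED is mapped back to HU through the inverse calibration, which must be
    strictly monotone in ED (otherwise a ``ValueError`` is raised); the HU
    grid is then written like an ordinary CT series.
    """
    hu = ed_to_hu(ed_grid, calibration)  # raises if calibration not invertible
    return write_ct_series(hu, directory, series_description="syCT (bulk ED)")


# ---------------------------------------------------------------------------
# auxiliary export
# ---------------------------------------------------------------------------

def save_nrrd(grid: VoxelGrid, file, *, dtype=None) -> Path:
    """Export a grid (e.g. a mask or label map) as NRRD for inspection."""
    import SimpleITK as sitk

    file = Path(file)
    file.parent.mkdir(parents=True, exist_ok=True)
    values = np.asarray(grid.values)
    if dtype is not None:
        values = values.astype(dtype)
    img = sitk.GetImageFromArray(values)
    img.SetSpacing(tuple(grid.spacing))
    img.SetOrigin(tuple(grid.origin))
    sitk.WriteImage(img, str(file), useCompression=False)
    return file
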