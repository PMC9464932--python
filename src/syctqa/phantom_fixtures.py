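"""Synthetic phantoms, structure sets and density-sensitive dose pairs.

Patient DICOM data cannot ship with a QA toolkit, so every pipeline stage is
exercised on generated phantoms: a body ellipsoid containing organ
primitives with distinct HU distributions, per-slice polygon contours
tracing each primitive's analytic boundary, and dose fields from a
deliberately simple surrogate dose model.

The surrogate is a broad-beam exponential-attenuation model: each beam
deposits ``weight × profile × exp(−μ_water × radiological path)`` where the
radiological path is the line integral of relative ED from the beam's entry
face to the voxel. It ignores scatter, beam hardening and magnetic-field
dose effects — it is a test fixture, not a dose engine. Its single load-
bearing property is monotone sensitivity to upstream density changes, which
is exactly what the syCT QA step has to detect.

``make_case`` assembles the five canonical study conditions: a concordant
patient, and the four documented failure modes (inhomogeneous lung target,
priority inversion that erases the skull, un-contoured support plate, and a
bulk ED that does not match the anatomy it is assigned to).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .dicom_io import ContourStructure
from .ed_model import DEFAULT_CALIBRATION, EDAssignment, EDCalibration, hu_to_ed
from .grid import AXIAL_ORIENTATION, VoxelGrid
from .structure_raster import StructureMask, rasterize
from .syct_builder import build_syct

__all__ = [
    "Primitive",
    "Beam",
    "PhantomSpec",
    "QACase",
    "make_phantom",
    "surrogate_dose",
    "make_case",
    "case_config",
    "CASE_KINDS",
]

MU_WATER = 0.005  # 1/mm, broad-beam effective attenuation of the surrogate
#: fixed, syntactically valid DICOM UID shared by all phantom fixtures
PHANTOM_FRAME_UID = "1.2.826.0.1.3680043.10.511.3.1"
_POLY_VERTICES = 96

CASE_KINDS = (
    "concordant",
    "lung_inhomogeneous",
    "priority_error",
    "missing_plate",
    "ed_mismatch",
)


@dataclass(frozen=True)
class Primitive:
    """One geometric organ primitive.

    ``size``: semi-axes (x, y, z) for an ellipsoid, (radius, radius,
    half-length) for a z-aligned cylinder, half-sizes for a box. A second
    HU population can occupy the half-space x ≥ center_x (``hu_mean2``),
    which is how the inhomogeneous lung target is built.
    """

    name: str
    kind: str  # ellipsoid | cylinder | box
    center: tuple[float, float, float]  # mm, (x, y, z)
    size: tuple[float, float, float]  # mm
    hu_mean: float
    hu_sigma: float = 0.0
    priority: int = 0
    hu_mean2: Optional[float] = None
    hu_sigma2: Optional[float] = None
    hole: Optional[tuple[float, float, float]] = None  # inner semi-axes (annulus)
    contoured: bool = True

    def inside(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        u = (x - self.center[0], y - self.center[1], z - self.center[2])
        if self.kind == "ellipsoid":
            r = (u[0] / self.size[0]) ** 2 + (u[1] / self.size[1]) ** 2 + (u[2] / self.size[2]) ** 2
            out = r <= 1.0
            if self.hole is not None:
                rin = (
                    (u[0] / self.hole[0]) ** 2
                    + (u[1] / self.hole[1]) ** 2
                    + (u[2] / self.hole[2]) ** 2
                )
                out &= rin > 1.0
            return out
        if self.kind == "cylinder":
            return ((u[0] / self.size[0]) ** 2 + (u[1] / self.size[1]) ** 2 <= 1.0) & (
                np.abs(u[2]) <= self.size[2]
            )
        if self.kind == "box":
            return (
                (np.abs(u[0]) <= self.size[0])
                & (np.abs(u[1]) <= self.size[1])
                & (np.abs(u[2]) <= self.size[2])
            )
        raise ValueError(f"unknown primitive kind '{self.kind}'")

    def slice_polygons(self, z: float) -> list[np.ndarray]:
        """Closed polygons tracing the boundary at slice plane z (mm)."""
        cx, cy, cz = self.center
        dzrel = z - cz
        theta = np.linspace(0, 2 * math.pi, _POLY_VERTICES, endpoint=False)
        if self.kind == "ellipsoid":
            t = dzrel / self.size[2]
            if abs(t) >= 1.0:
                return []
            shrink = math.sqrt(1 - t * t)
            ax, ay = self.size[0] * shrink, self.size[1] * shrink
            if min(ax, ay) < 1e-6:
                return []
            polys = [_ring(cx, cy, ax, ay, z, theta)]
            if self.hole is not None:
                ti = dzrel / self.hole[2]
                if abs(ti) < 1.0:
                    si = math.sqrt(1 - ti * ti)
                    polys.append(_ring(cx, cy, self.hole[0] * si, self.hole[1] * si, z, theta))
            return polys
        if self.kind == "cylinder":
            if abs(dzrel) > self.size[2]:
                return []
            return [_ring(cx, cy, self.size[0], self.size[1], z, theta)]
        if self.kind == "box":
            if abs(dzrel) > self.size[2]:
                return []
            hx, hy = self.size[0], self.size[1]
            corners = np.array(
                [
                    [cx - hx, cy - hy, z],
                    [cx + hx, cy - hy, z],
                    [cx + hx, cy + hy, z],
                    [cx - hx, cy + hy, z],
                ]
            )
            return [corners]
        raise ValueError(f"unknown primitive kind '{self.kind}'")


def _ring(cx: float, cy: float, ax: float, ay: float, z: float, theta: np.ndarray) -> np.ndarray:
    return np.column_stack([cx + ax * np.cos(theta), cy + ay * np.sin(theta), np.full_like(theta, z)])


@dataclass(frozen=True)
class Beam:
    """One broad beam: axis-aligned propagation, rectangular aperture.

    ``axis`` ∈ {"x+", "x-", "y+", "y-"} is the propagation direction (the
    beam enters at the opposite grid face). The aperture is ``width`` mm
    across the in-plane perpendicular axis and ``height`` mm along z,
    centered on ``center``, with a Gaussian penumbra of ``penumbra`` mm.
    """

    axis: str
    width: float
    height: float
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    weight: float = 1.0
    penumbra: float = 3.0

    def __post_init__(self) -> None:
        if self.axis not in {"x+", "x-", "y+", "y-"}:
            raise ValueError(f"beam axis must be one of x+/x-/y+/y-, got '{self.axis}'")


@dataclass
class PhantomSpec:
    """Full description of one synthetic patient."""

    shape: tuple[int, int, int] = (24, 48, 48)  # (nz, ny, nx)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)  # (dx, dy, dz)
    primitives: list[Primitive] = field(default_factory=list)
    beams: list[Beam] = field(default_factory=list)
    background_hu: float = -1000.0
    seed: int = 0

    def grid_geometry(self) -> VoxelGrid:
        nz, ny, nx = self.shape
        dx, dy, dz = self.spacing
        origin = (-(nx - 1) / 2 * dx, -(ny - 1) / 2 * dy, -(nz - 1) / 2 * dz)
        return VoxelGrid(
            np.zeros(self.shape), self.spacing, origin, AXIAL_ORIENTATION, PHANTOM_FRAME_UID
        )


def make_phantom(
    spec: PhantomSpec,
) -> tuple[VoxelGrid, list[ContourStructure], list[StructureMask]]:
    """Voxelize a phantom spec into (CT, contour structures, masks).

    Primitives are painted in list order (later wins for the CT values);
    Gaussian HU noise with each primitive's sigma is added in a single
    deterministic draw from ``spec.seed``. Contours trace the analytic
    boundaries slice by slice; masks are obtained by rasterizing those
    contours onto the CT grid, exactly as the pipeline will.
    """
    geo = spec.grid_geometry()
    zc, yc, xc = geo.axis_coords()
    zz, yy, xx = np.meshgrid(zc, yc, xc, indexing="ij")

    hu = np.full(spec.shape, spec.background_hu, dtype=np.float64)
    sigma = np.zeros(spec.shape)
    for p in spec.primitives:
        ins = p.inside(xx, yy, zz)
        if p.hu_mean2 is not None:
            right = ins & (xx >= p.center[0])
            left = ins & ~right
            hu[left] = p.hu_mean
            hu[right] = p.hu_mean2
            sigma[left] = p.hu_sigma
            sigma[right] = p.hu_sigma2 if p.hu_sigma2 is not None else p.hu_sigma
        else:
            hu[ins] = p.hu_mean
            sigma[ins] = p.hu_sigma
    rng = np.random.default_rng(spec.seed)
    hu = np.round(hu + rng.standard_normal(spec.shape) * sigma)  # CT stores integer HU

    ct = VoxelGrid(hu, spec.spacing, geo.origin, AXIAL_ORIENTATION, PHANTOM_FRAME_UID)

    structures: list[ContourStructure] = []
    for p in spec.primitives:
        if not p.contoured:
            continue
        contours: list[np.ndarray] = []
        for z in zc:
            contours.extend(p.slice_polygons(float(z)))
        structures.append(ContourStructure(name=p.name, contours=contours))
    masks = [rasterize(s, ct) for s in structures]
    return ct, structures, masks


# ---------------------------------------------------------------------------
# surrogate dose model
# ---------------------------------------------------------------------------

def _radiological_path(ed: np.ndarray, axis: str, spacing: tuple[float, float, float]) -> np.ndarray:
    """Line integral of ED (in ED·mm) from the beam entry face to each voxel
    center, exact for the piecewise-constant voxel density model."""
    dx, dy, dz = spacing
    arr_axis, step = {"x": (2, dx), "y": (1, dy)}[axis[0]]
    vals = ed if axis[1] == "+" else np.flip(ed, axis=arr_axis)
    csum = np.cumsum(vals, axis=arr_axis) * step
    path = csum - vals * (step / 2.0)  # up to the voxel center, not its far face
    if axis[1] == "-":
        path = np.flip(path, axis=arr_axis)
    return path


def _aperture(beam: Beam, grid: VoxelGrid) -> np.ndarray:
    """In-plane beam profile (broadcastable to the grid): boxcar aperture
    smoothed with a Gaussian penumbra."""
    zc, yc, xc = grid.axis_coords()
    cx, cy, cz = beam.center
    if beam.axis[0] == "x":
        lateral, lat_c, lat_spacing, lat_axis = yc, cy, grid.spacing[1], 1
    else:
        lateral, lat_c, lat_spacing, lat_axis = xc, cx, grid.spacing[0], 2
    lat = (np.abs(lateral - lat_c) <= beam.width / 2).astype(float)
    vert = (np.abs(zc - cz) <= beam.height / 2).astype(float)
    prof2d = vert[:, None] * lat[None, :]
    sig = (beam.penumbra / grid.spacing[2], beam.penumbra / lat_spacing)
    prof2d = ndimage.gaussian_filter(prof2d, sigma=sig, mode="constant")
    if lat_axis == 1:  # profile varies over (z, y); constant along x
        return prof2d[:, :, None]
    return prof2d[:, None, :]  # varies over (z, x); constant along y


def surrogate_dose(
    ed: VoxelGrid, beams: Sequence[Beam], mu_water: float = MU_WATER
) -> VoxelGrid:
    """Broad-beam exponential-attenuation dose of a beam set on an ED grid.

    dose(v) = Σ_b weight_b · profile_b(v) · exp(−μ_water · path_b(v)), with
    path_b the radiological depth of the voxel center along the beam axis.
    Deterministic; monotone non-increasing in every upstream ED value.
    """
    if not beams:
        raise ValueError("at least one beam is required")
    ed_vals = np.asarray(ed.values, dtype=np.float64)
    if ed_vals.min() < -1e-9:
        raise ValueError("relative ED must be non-negative")
    dose = np.zeros(ed.shape)
    for b in beams:
        path = _radiological_path(ed_vals, b.axis, ed.spacing)
        dose += b.weight * _aperture(b, ed) * np.exp(-mu_water * path)
    return ed.with_values(dose)


# ---------------------------------------------------------------------------
# canonical QA cases
# ---------------------------------------------------------------------------

@dataclass
class QACase:
    """A complete fixture: inputs for the QA pipeline plus its provenance."""

    kind: str
    spec: PhantomSpec
    ct: VoxelGrid
    structures: list[ContourStructure]
    masks: list[StructureMask]
    assignments: list[EDAssignment]
    ref_dose: VoxelGrid
    eval_dose: VoxelGrid
    prescription_dose: float
    targets: list[str]
    oars: list[str]
    body_name: str = "Body"


def _base_primitives() -> list[Primitive]:
    return [
        Primitive("Body", "ellipsoid", (0, 0, 0), (62, 55, 60), hu_mean=0, hu_sigma=15, priority=1),
        Primitive("Cord", "cylinder", (-35, 10, 0), (6, 6, 40), hu_mean=35, hu_sigma=10, priority=2),
        Primitive("Organ", "ellipsoid", (-10, -25, 0), (18, 14, 20), hu_mean=55, hu_sigma=10, priority=3),
        Primitive("Target", "ellipsoid", (25, 0, 0), (12, 12, 12), hu_mean=40, hu_sigma=12, priority=4),
    ]


def _base_beams() -> list[Beam]:
    return [
        Beam("x+", width=44, height=30, center=(25, 0, 0), weight=1.0),
        Beam("x-", width=44, height=30, center=(25, 0, 0), weight=1.0),
        Beam("y+", width=44, height=30, center=(25, 0, 0), weight=1.0),
    ]


def _case_spec(kind: str, seed: int) -> tuple[PhantomSpec, dict]:
    prims = _base_primitives()
    extras: dict = {"ed_overrides": {}, "uncontoured": []}
    if kind == "concordant":
        pass
    elif kind == "lung_inhomogeneous":
        prims.insert(
            1,
            Primitive("Lung", "ellipsoid", (25, 5, 0), (34, 30, 28), hu_mean=-700, hu_sigma=30, priority=5),
        )
        # split target: aerated half vs solid half — the high internal ED
        # gradient a single bulk ED cannot represent
        prims[-1] = replace(
            prims[-1],
            size=(13.0, 13.0, 13.0),
            hu_mean=-750.0,
            hu_sigma=30.0,
            hu_mean2=100.0,
            hu_sigma2=15.0,
            priority=6,
        )
    elif kind == "priority_error":
        # paint order: body, then brain over the full head, then the skull
        # shell back on top, so the CT shows bone. The error is in the
        # *assignment table*: the whole-brain ROI (the full outer ellipsoid)
        # outranks the skull it encloses.
        prims = [
            prims[0],
            Primitive("Brain", "ellipsoid", (0, -5, 0), (40, 35, 28), hu_mean=30, hu_sigma=10, priority=5),
            Primitive(
                "Skull", "ellipsoid", (0, -5, 0), (40, 35, 28),
                hu_mean=300, hu_sigma=30, priority=2, hole=(32, 27, 22),
            ),
            Primitive("Target", "ellipsoid", (5, -5, 0), (8, 8, 8), hu_mean=35, hu_sigma=8, priority=6),
        ]
    elif kind == "missing_plate":
        prims.append(
            Primitive(
                "Plate", "box", (0, 62, 0), (45, 7, 34),
                hu_mean=400, hu_sigma=15, priority=9, contoured=False,
            )
        )
    elif kind == "ed_mismatch":
        extras["ed_overrides"]["Organ"] = 0.2  # bulk ED off by +0.2 vs the anatomy
    else:
        raise ValueError(f"unknown case kind '{kind}'; expected one of {CASE_KINDS}")

    beams = _base_beams()
    if kind == "lung_inhomogeneous":
        # non-opposed beams: opposed pairs cancel heterogeneity errors to
        # first order and would mask the bulk-assignment failure
        beams = [
            Beam("x+", width=44, height=30, center=(25, 0, 0), weight=1.0),
            Beam("y+", width=44, height=30, center=(25, 0, 0), weight=1.0),
        ]
    if kind == "missing_plate":
        beams = [
            Beam("y-", width=50, height=30, center=(0, 0, 0), weight=1.0),
            Beam("x+", width=44, height=30, center=(25, 0, 0), weight=1.0),
            Beam("x-", width=44, height=30, center=(25, 0, 0), weight=1.0),
        ]
    if kind == "priority_error":
        beams = [
            Beam("x+", width=40, height=26, center=(5, -5, 0), weight=1.0),
            Beam("x-", width=40, height=26, center=(5, -5, 0), weight=1.0),
            Beam("y+", width=40, height=26, center=(5, -5, 0), weight=1.0),
        ]
    spec = PhantomSpec(primitives=prims, beams=beams, seed=seed)
    return spec, extras


def make_case(
    kind: str,
    seed: int = 0,
    calibration: EDCalibration = DEFAULT_CALIBRATION,
    prescription_dose: float = 25.0,
) -> QACase:
    """Build one canonical QA fixture.

    The reference dose is the surrogate model on the CT's true voxelwise ED;
    the evaluated dose is the same beam set — identically weighted, i.e.
    recalculated, not reoptimized — on the bulk-assigned syCT. Beam weights
    are scaled once so the reference mean target dose equals the
    prescription (default 25 Gy).
    """
    spec, extras = _case_spec(kind, seed)
    ct, structures, masks = make_phantom(spec)
    by_name = {m.name: m for m in masks}

    assignments = []
    for p in spec.primitives:
        if not p.contoured:
            continue
        assignments.append(EDAssignment(p.name, p.priority, None))

    syct = build_syct(ct, masks, assignments, calibration, background_ed=0.0)
    if extras["ed_overrides"]:
        # re-issue the table with the deliberately wrong bulk values
        wrong = []
        for a in syct.assignment_table:
            shift = extras["ed_overrides"].get(a.structure_name, 0.0)
            wrong.append(EDAssignment(a.structure_name, a.priority, a.mean_ed + shift))
        assignments = wrong
        syct = build_syct(ct, masks, assignments, calibration, background_ed=0.0)
    else:
        assignments = syct.assignment_table

    true_ed = hu_to_ed(ct, calibration)
    ref = surrogate_dose(true_ed, spec.beams)
    target_mask = by_name["Target"].mask
    scale = prescription_dose / float(np.asarray(ref.values)[target_mask].mean())
    ref = ref.with_values(ref.values * scale)
    ev = surrogate_dose(syct.ed_grid, spec.beams)
    ev = ev.with_values(ev.values * scale)

    oars = [m.name for m in masks if m.name not in ("Body", "Target")]
    return QACase(
        kind=kind,
        spec=spec,
        ct=ct,
        structures=structures,
        masks=masks,
        assignments=list(assignments),
        ref_dose=ref,
        eval_dose=ev,
        prescription_dose=prescription_dose,
        targets=["Target"],
        oars=oars,
    )


def case_config(case: QACase):
    """The QA configuration matching a generated case.

    Metric table: prescription coverage plus D/V parameters for the target,
    Dmax/Dmean for each OAR — the shape of a typical clinical constraint
    list.
    """
    from .qa_pipeline import QAConfig

    pre = 0.95 * case.prescription_dose
    return QAConfig(
        assignments=case.assignments,
        body=case.body_name,
        targets=case.targets,
        oars=case.oars,
        metrics={
            "Target": [f"VDpre@{pre:g}Gy", "Dmax", "Dmean", "D95%", "D50%"],
            **{o: ["Dmax", "Dmean"] for o in case.oars},
        },
        prescription_dose=case.prescription_dose,
    )


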