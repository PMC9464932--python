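"""Ideal synthetic-CT generation by bulk density assignment.

The "ideal" syCT audits the best case of MR-Linac adaptive recalculation:
it is built from the reference CT's own contours, so any dosimetric
difference between a plan recalculated on it and the reference plan is the
error intrinsic to bulk density assignment itself, with registration and
recontouring excluded. Every voxel of each contoured structure is forced to
the structure's mean relative ED; overlaps are resolved by the plan's
priority table; voxels outside all structures get the background ED
(default air, 0.0 — anything not contoured does not exist dosimetrically,
which is exactly the lesson of un-contoured support hardware).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ed_model import DEFAULT_CALIBRATION, EDAssignment, EDCalibration, mean_ed
from .grid import VoxelGrid
from .structure_raster import PriorityLabelMap, StructureMask, resolve_priorities

logger = logging.getLogger(__name__)

__all__ = ["SyctResult", "Finding", "build_syct", "coverage_check"]


@dataclass
class Finding:
    """One advisory troubleshooting observation (never changes a verdict)."""

    code: str
    structure: str
    detail: str
    data: dict = field(default_factory=dict)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.structure}: {self.detail}"


@dataclass
class SyctResult:
    """Outcome of bulk assignment: the ED grid plus its full provenance."""

    ed_grid: VoxelGrid
    label_map: PriorityLabelMap
    assignment_table: list[EDAssignment]
    coverage_report: dict

    def assigned_ed(self, structure_name: str) -> float:
        for a in self.assignment_table:
            if a.structure_name == structure_name:
                return a.mean_ed
        raise KeyError(f"no assignment for '{structure_name}'")


def build_syct(
    ct: VoxelGrid,
    structures: Sequence[StructureMask],
    assignments: Sequence[EDAssignment],
    calibration: EDCalibration = DEFAULT_CALIBRATION,
    background_ed: float = 0.0,
    *,
    round_decimals: Optional[int] = 3,
) -> SyctResult:
    """Build the ideal syCT from a reference CT, masks and an assignment table.

    Each voxel's ED equals the mean ED of the highest-priority structure
    covering it, else ``background_ed``. Assignments without an explicit
    ``mean_ed`` are computed from the reference CT over the structure's
    mask and (by default) rounded to 3 decimals, matching typical TPS
    display precision so reports are reproducible.

    Raises ``ValueError`` for an assignment naming an unknown structure;
    empty structures are skipped with a warning.
    """
    by_name = {m.name: m for m in structures}
    missing = [a.structure_name for a in assignments if a.structure_name not in by_name]
    if missing:
        raise ValueError(f"assignments name structures absent from the set: {missing}")

    applied: list[EDAssignment] = []
    masks: list[StructureMask] = []
    for a in assignments:
        m = by_name[a.structure_name]
        if not m.mask.any():
            logger.warning("structure '%s' is empty; skipping its assignment", a.structure_name)
            continue
        ed = a.mean_ed if a.mean_ed is not None else mean_ed(ct, m.mask, calibration)
        if round_decimals is not None:
            ed = round(float(ed), round_decimals)
        applied.append(EDAssignment(a.structure_name, a.priority, float(ed)))
        masks.append(m.with_priority(a.priority))

    if not masks:
        raise ValueError("no non-empty assigned structures; cannot build a syCT")

    label_map = resolve_priorities(masks)
    ed_values = np.full(ct.shape, float(background_ed), dtype=np.float64)
    ed_by_name = {a.structure_name: a.mean_ed for a in applied}
    for lab, name in label_map.legend.items():
        ed_values[label_map.labels == lab] = ed_by_name[name]

    n_total = int(np.prod(ct.shape))
    n_bg = int((label_map.labels == 0).sum())
    coverage = {
        "structure_voxels": {
            name: int((label_map.labels == lab).sum()) for lab, name in label_map.legend.items()
        },
        "background_fraction": n_bg / n_total,
        "assigned_fraction": 1.0 - n_bg / n_total,
    }
    ed_grid = ct.with_values(ed_values)
    return SyctResult(
        ed_grid=ed_grid,
        label_map=label_map,
        assignment_table=applied,
        coverage_report=coverage,
    )


def coverage_check(
    syct: SyctResult, body_name: str, body_mask: Optional[np.ndarray] = None
) -> list[Finding]:
    """Audit how the bulk assignment covers the grid relative to the body.

    Reports (a) body voxels left unlabelled (an internal-consistency check:
    impossible when the body itself is assigned), (b) structures whose
    winning voxels lie outside the body mask (support hardware — these must
    carry an intentional assignment, so the finding is informational). The
    fraction of the grid left at background ED is part of the builder's
    coverage report.

    ``body_mask`` is the body structure's own rasterized mask; when omitted
    the body's labelled voxels are used instead, which understates the body
    wherever higher-priority organs are nested inside it.
    """
    findings: list[Finding] = []
    labels = syct.label_map.labels
    try:
        body_label = syct.label_map.label_of(body_name)
    except KeyError:
        findings.append(
            Finding(
                "BODY_NOT_ASSIGNED",
                body_name,
                f"body structure '{body_name}' is not in the assignment table",
            )
        )
        return findings

    body = np.asarray(body_mask, dtype=bool) if body_mask is not None else labels == body_label
    unlabelled_in_body = int((body & (labels == 0)).sum())
    if unlabelled_in_body:
        findings.append(
            Finding(
                "BODY_VOXELS_UNLABELLED",
                body_name,
                f"{unlabelled_in_body} voxels inside the body carry no assignment",
                {"voxels": unlabelled_in_body},
            )
        )
    for lab, name in syct.label_map.legend.items():
        if name == body_name:
            continue
        outside = int(((labels == lab) & ~body).sum())
        if outside > 0:
            findings.append(
                Finding(
                    "STRUCTURE_OUTSIDE_BODY",
                    name,
                    f"structure outside body: {name} ({outside} voxels)",
                    {"voxels_outside_body": outside},
                )
            )
    return findings
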