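"""Orchestration of the full syCT quality-control step.

``run_qa`` ties the whole workflow together: rasterize the plan's contours,
build the ideal syCT, difference the reference and recalculated dose
distributions via DVH parameters and 3D gamma analysis, apply the clinical
tolerance rules, and attach advisory troubleshooting findings for the
documented failure modes.

Agreement rule: the plan pair is in agreement when the body gamma pass rate
at 3 %/3 mm is higher than 99 % AND every point of each target's DVH agrees
within 1.5 %-volume or 1 Gy of dose AND every listed V-type parameter delta
is lower than 1.5 % AND every listed D-type parameter delta is lower than
1 Gy (strict inequalities throughout). The 2 %/2 mm gamma analysis is
always computed and reported but never gates the verdict.

The "any point of the DVH" clause is evaluated as a band test — the curves
agree at a point when they are within 1.5 %-volume of each other somewhere
inside a ±1 Gy dose window — because a purely vertical gap would fail any
steep target DVH on a clinically negligible dose shift. The plain maximum
vertical gap is still reported for every structure in the metric table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .dicom_io import ContourStructure
from .ed_model import (
    DEFAULT_CALIBRATION,
    EDAssignment,
    EDCalibration,
    ed_stats,
    mean_ed,
)
from .dvh_engine import MetricDelta, compare_plans, dvh_band_gap
from .gamma_engine import GammaCriteria, GammaResult, gamma_index, pass_rate
from .grid import VoxelGrid
from .structure_raster import StructureMask, rasterize
from .syct_builder import Finding, SyctResult, build_syct, coverage_check

logger = logging.getLogger(__name__)

__all__ = [
    "ToleranceCriteria",
    "TroubleshootThresholds",
    "QAConfig",
    "Clause",
    "QAReport",
    "run_qa",
    "troubleshoot",
    "classify_cohort",
]


@dataclass(frozen=True)
class ToleranceCriteria:
    """Agreement thresholds of the QA verdict (strict inequalities)."""

    gamma_pass_min: float = 99.0  # % of points with γ < 1, at the gating criteria
    dvh_pct_max: float = 1.5  # %-volume, V-type deltas and DVH gaps
    dvh_gy_max: float = 1.0  # Gy, D-type deltas
    apply_dvh_rule_to: tuple[str, ...] = ("targets", "oars")

    def __post_init__(self) -> None:
        if min(self.gamma_pass_min, self.dvh_pct_max, self.dvh_gy_max) <= 0:
            raise ValueError("all tolerance thresholds must be positive")


@dataclass(frozen=True)
class TroubleshootThresholds:
    """Trigger levels of the advisory troubleshooting heuristics."""

    inhomogeneity_std: float = 0.15  # ED std flagging a structure as inhomogeneous
    shadow_coverage: float = 0.95  # fraction covered by one higher-priority structure
    ed_mismatch: float = 0.05  # |assigned − recomputed| mean ED
    hardware_hu: float = 200.0  # dense-voxel threshold outside all structures
    hardware_min_voxels: int = 20
    inhomogeneity_classes: tuple[str, ...] = ("targets",)


@dataclass
class QAConfig:
    """Everything run_qa needs beyond the four input objects."""

    assignments: list[EDAssignment]
    body: str = "Body"
    targets: list[str] = field(default_factory=list)
    oars: list[str] = field(default_factory=list)
    metrics: dict[str, list[str]] = field(default_factory=dict)
    prescription_dose: Optional[float] = None
    calibration: EDCalibration = DEFAULT_CALIBRATION
    background_ed: float = 0.0
    gamma_criteria: list[GammaCriteria] = field(
        default_factory=lambda: [GammaCriteria(3.0, 3.0), GammaCriteria(2.0, 2.0)]
    )
    gamma_region: str = "body"  # "body" or "grid"
    tolerances: ToleranceCriteria = ToleranceCriteria()
    troubleshoot: TroubleshootThresholds = TroubleshootThresholds()
    dvh_bin_width: float = 0.01

    def structure_class(self, name: str) -> str:
        if name == self.body:
            return "body"
        if name in self.targets:
            return "targets"
        if name in self.oars:
            return "oars"
        return "other"

    def digest(self) -> str:
        """Stable hash of the config for report provenance."""
        blob = json.dumps(_plain(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "QAConfig":
        """Build a config from a plain (YAML-loaded) mapping.

        Recognized keys mirror the dataclass fields; assignments are given
        as ``[{name, priority, ed?}]``, the calibration as ``[[HU, ED]]``
        pairs, gamma criteria as ``[[dose%, dta_mm]]`` pairs with optional
        shared numerical settings under ``gamma``.
        """
        assignments = [
            EDAssignment(a["name"], int(a["priority"]), a.get("ed"))
            for a in d.get("assignments", [])
        ]
        calibration = (
            EDCalibration(tuple((float(h), float(e)) for h, e in d["calibration"]))
            if "calibration" in d
            else DEFAULT_CALIBRATION
        )
        gamma_extra = d.get("gamma", {})
        criteria = [
            GammaCriteria(float(dc), float(dta), **gamma_extra)
            for dc, dta in d.get("gamma_criteria", [[3.0, 3.0], [2.0, 2.0]])
        ]
        tolerances = ToleranceCriteria(**d["tolerances"]) if "tolerances" in d else ToleranceCriteria()
        ts = d.get("troubleshoot", {})
        if "inhomogeneity_classes" in ts:
            ts = {**ts, "inhomogeneity_classes": tuple(ts["inhomogeneity_classes"])}
        troubleshoot_thresholds = TroubleshootThresholds(**ts) if ts else TroubleshootThresholds()
        return cls(
            assignments=assignments,
            body=d.get("body", "Body"),
            targets=list(d.get("targets", [])),
            oars=list(d.get("oars", [])),
            metrics={k: list(v) for k, v in d.get("metrics", {}).items()},
            prescription_dose=d.get("prescription_dose"),
            calibration=calibration,
            background_ed=float(d.get("background_ed", 0.0)),
            gamma_criteria=criteria,
            gamma_region=d.get("gamma_region", "body"),
            tolerances=tolerances,
            troubleshoot=troubleshoot_thresholds,
            dvh_bin_width=float(d.get("dvh_bin_width", 0.01)),
        )

    def to_dict(self) -> dict:
        """Plain mapping suitable for YAML serialization (inverse of from_dict)."""
        return {
            "assignments": [
                {"name": a.structure_name, "priority": a.priority, "ed": a.mean_ed}
                for a in self.assignments
            ],
            "body": self.body,
            "targets": list(self.targets),
            "oars": list(self.oars),
            "metrics": {k: list(v) for k, v in self.metrics.items()},
            "prescription_dose": self.prescription_dose,
            "calibration": [list(p) for p in self.calibration.anchor_points],
            "background_ed": self.background_ed,
            "gamma_criteria": [[c.dose_criterion, c.dta] for c in self.gamma_criteria],
            "gamma_region": self.gamma_region,
            "tolerances": {
                "gamma_pass_min": self.tolerances.gamma_pass_min,
                "dvh_pct_max": self.tolerances.dvh_pct_max,
                "dvh_gy_max": self.tolerances.dvh_gy_max,
            },
            "troubleshoot": {
                "inhomogeneity_std": self.troubleshoot.inhomogeneity_std,
                "shadow_coverage": self.troubleshoot.shadow_coverage,
                "ed_mismatch": self.troubleshoot.ed_mismatch,
                "hardware_hu": self.troubleshoot.hardware_hu,
                "hardware_min_voxels": self.troubleshoot.hardware_min_voxels,
                "inhomogeneity_classes": list(self.troubleshoot.inhomogeneity_classes),
            },
            "dvh_bin_width": self.dvh_bin_width,
        }


def _plain(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


@dataclass
class Clause:
    """One tolerance clause with the numbers that decide it (auditable)."""

    name: str
    structure: str
    value: Optional[float]
    threshold: float
    passed: bool
    unit: str = ""


@dataclass
class QAReport:
    """Full outcome of one QA run."""

    verdict: str  # PASS | FAIL
    clauses: list[Clause]
    gamma_pass_rates: dict[str, dict[str, Optional[float]]]  # criteria label -> mask -> %
    metric_deltas: list[MetricDelta]
    dvh_gaps: dict[str, float]  # structure -> max %-volume gap
    findings: list[Finding]
    provenance: dict

    def failed_clauses(self) -> list[Clause]:
        return [c for c in self.clauses if not c.passed]

    def finding_codes(self) -> set[str]:
        return {f.code for f in self.findings}

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "clauses": [_plain(c) for c in self.clauses],
            "gamma_pass_rates": self.gamma_pass_rates,
            "metric_deltas": [
                {
                    "structure": d.structure_name,
                    "metric": d.metric.label,
                    "ref": d.ref_value,
                    "eval": d.eval_value,
                    "delta": d.delta,
                    "unit": d.unit,
                }
                for d in self.metric_deltas
            ],
            "dvh_gaps": self.dvh_gaps,
            "findings": [_plain(f) for f in self.findings],
            "provenance": self.provenance,
        }


def run_qa(
    ct: VoxelGrid,
    structures: Sequence[ContourStructure] | Sequence[StructureMask],
    ref_dose: VoxelGrid,
    eval_dose: VoxelGrid,
    config: QAConfig,
) -> QAReport:
    """Run the complete quality-control step on one plan pair.

    ``structures`` may be contour structures (rasterized here onto the CT
    grid) or pre-rasterized masks. ``eval_dose`` is the plan recalculated on
    the syCT by the external dose engine (or the fixture surrogate); both
    dose grids are trilinearly resampled onto the CT grid when their
    geometry differs. Raises before any analysis when the body or a declared
    target structure is missing.
    """
    if structures and isinstance(structures[0], StructureMask):
        masks = list(structures)
    else:
        masks = [rasterize(s, ct) for s in structures]
    by_name = {m.name: m for m in masks}

    required = [config.body, *config.targets]
    missing = [n for n in required if n not in by_name]
    if missing:
        raise ValueError(f"required structures missing from the structure set: {missing}")

    ref = ref_dose.resample_to(ct) if not ref_dose.same_geometry(ct) else ref_dose
    ev = eval_dose.resample_to(ct) if not eval_dose.same_geometry(ct) else eval_dose

    # ideal syCT (for troubleshooting and coverage findings)
    syct = build_syct(ct, masks, config.assignments, config.calibration, config.background_ed)

    # DVH comparison over the structures listed in the metric table
    metric_masks = [by_name[n] for n in config.metrics if n in by_name]
    deltas, gaps = compare_plans(
        ref, ev, metric_masks, config.metrics, config.prescription_dose, config.dvh_bin_width
    )

    # gamma analysis at every requested criteria pair
    body_mask = by_name[config.body].mask
    region = body_mask if config.gamma_region == "body" else None
    rate_masks = [by_name[config.body]] + [
        by_name[n] for n in (*config.targets, *config.oars) if n in by_name
    ]
    gamma_rates: dict[str, dict[str, Optional[float]]] = {}
    gamma_results: dict[str, GammaResult] = {}
    for crit in config.gamma_criteria:
        res = gamma_index(ref, ev, crit, region=region)
        gamma_results[crit.label] = res
        rates = {m.name: pass_rate(res, m) for m in rate_masks}
        res.pass_rates = rates
        gamma_rates[crit.label] = rates

    # tolerance clauses
    tol = config.tolerances
    clauses: list[Clause] = []
    gating = config.gamma_criteria[0].label
    body_rate = gamma_rates[gating][config.body]
    clauses.append(
        Clause(
            name=f"gamma {gating} body pass rate > {tol.gamma_pass_min:g}%",
            structure=config.body,
            value=body_rate,
            threshold=tol.gamma_pass_min,
            passed=body_rate is not None and body_rate > tol.gamma_pass_min,
            unit="%",
        )
    )
    band_gaps: dict[str, float] = {}
    for name in config.targets:
        if name in gaps:
            band_gaps[name] = dvh_band_gap(
                ref, ev, by_name[name], dose_window=tol.dvh_gy_max, bin_width=config.dvh_bin_width
            )
            clauses.append(
                Clause(
                    name=(
                        f"target DVH any-point difference < {tol.dvh_pct_max:g}% "
                        f"(or {tol.dvh_gy_max:g} Gy)"
                    ),
                    structure=name,
                    value=band_gaps[name],
                    threshold=tol.dvh_pct_max,
                    passed=band_gaps[name] < tol.dvh_pct_max,
                    unit="%",
                )
            )
    for d in deltas:
        if config.structure_class(d.structure_name) not in tol.apply_dvh_rule_to:
            continue
        limit = tol.dvh_gy_max if d.unit == "Gy" else tol.dvh_pct_max
        clauses.append(
            Clause(
                name=f"Δ{d.metric.label} < {limit:g} {d.unit}",
                structure=d.structure_name,
                value=d.delta,
                threshold=limit,
                passed=d.delta < limit,
                unit=d.unit,
            )
        )

    verdict = "PASS" if all(c.passed for c in clauses) else "FAIL"

    findings = coverage_check(syct, config.body, body_mask)
    findings += troubleshoot(
        ct, masks, config.assignments, syct, config.calibration, config.troubleshoot, config
    )

    provenance = {
        "package": f"syctqa {__version__}",
        "config_digest": config.digest(),
        "grid_shape": list(ct.shape),
        "grid_spacing": list(ct.spacing),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    return QAReport(
        verdict=verdict,
        clauses=clauses,
        gamma_pass_rates=gamma_rates,
        metric_deltas=deltas,
        dvh_gaps=gaps,
        findings=findings,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# troubleshooting heuristics
# ---------------------------------------------------------------------------

def troubleshoot(
    ct: VoxelGrid,
    masks: Sequence[StructureMask],
    assignments: Sequence[EDAssignment],
    syct: SyctResult,
    calibration: EDCalibration = DEFAULT_CALIBRATION,
    thresholds: TroubleshootThresholds = TroubleshootThresholds(),
    config: Optional[QAConfig] = None,
) -> list[Finding]:
    """Advisory diagnostics for the documented syCT failure modes.

    * ``INHOMOGENEOUS_STRUCTURE`` — a structure (by default: targets) whose
      internal ED spread exceeds the threshold; a single bulk ED cannot
      represent it (the lung-target signature).
    * ``PRIORITY_SHADOWING`` — a structure almost entirely covered by a
      single higher-priority structure, so its bulk ED never reaches the
      syCT (the lost-skull signature).
    * ``ED_MISMATCH`` — an assigned bulk ED far from the value recomputed
      from the CT under the contour, as happens when contours were drawn on
      a different image.
    * ``UNASSIGNED_HARDWARE`` — dense CT voxels outside every structure
      (or labelled voxels outside the body): support hardware that will
      silently vanish from the syCT.

    Findings are advisory and never alter the verdict.
    """
    findings: list[Finding] = []
    by_name = {m.name: m for m in masks}
    prio = {a.structure_name: a.priority for a in assignments}

    def in_class(name: str) -> bool:
        if config is None:
            return True
        return config.structure_class(name) in thresholds.inhomogeneity_classes

    for a in assignments:
        m = by_name.get(a.structure_name)
        if m is None or not m.mask.any():
            continue
        if in_class(a.structure_name):
            stats = ed_stats(ct, m.mask, calibration)
            if stats["std"] > thresholds.inhomogeneity_std:
                findings.append(
                    Finding(
                        "INHOMOGENEOUS_STRUCTURE",
                        a.structure_name,
                        f"ED std {stats['std']:.3f} exceeds {thresholds.inhomogeneity_std:g} "
                        f"(range {stats['min']:.2f}–{stats['max']:.2f}); a single bulk ED "
                        "cannot represent this structure",
                        stats,
                    )
                )
        if a.mean_ed is not None:
            recomputed = mean_ed(ct, m.mask, calibration)
            if abs(a.mean_ed - recomputed) > thresholds.ed_mismatch:
                findings.append(
                    Finding(
                        "ED_MISMATCH",
                        a.structure_name,
                        f"assigned mean ED {a.mean_ed:.3f} vs {recomputed:.3f} recomputed "
                        "from the CT under the contour — were the contours drawn on "
                        "a different image?",
                        {"assigned": a.mean_ed, "recomputed": recomputed},
                    )
                )

    for a in assignments:
        m = by_name.get(a.structure_name)
        if m is None or not m.mask.any():
            continue
        n_own = int(m.mask.sum())
        for b in assignments:
            if b.structure_name == a.structure_name or prio[b.structure_name] <= prio[a.structure_name]:
                continue
            other = by_name.get(b.structure_name)
            if other is None:
                continue
            covered = int((m.mask & other.mask).sum()) / n_own
            if covered >= thresholds.shadow_coverage:
                findings.append(
                    Finding(
                        "PRIORITY_SHADOWING",
                        a.structure_name,
                        f"{100 * covered:.1f}% of '{a.structure_name}' is covered by the "
                        f"higher-priority '{b.structure_name}'; its bulk ED is lost on the syCT",
                        {"covered_fraction": covered, "shadowed_by": b.structure_name},
                    )
                )

    any_structure = np.zeros(ct.shape, dtype=bool)
    for m in masks:
        any_structure |= m.mask
    dense_outside = (np.asarray(ct.values) > thresholds.hardware_hu) & ~any_structure
    n_dense = int(dense_outside.sum())
    if n_dense >= thresholds.hardware_min_voxels:
        findings.append(
            Finding(
                "UNASSIGNED_HARDWARE",
                "",
                f"{n_dense} voxels above {thresholds.hardware_hu:g} HU lie outside every "
                "structure (support hardware?); they will be background on the syCT",
                {"dense_voxels_outside_structures": n_dense},
            )
        )
    return findings


def classify_cohort(reports: Sequence[QAReport]) -> dict:
    """Aggregate a batch of QA reports into cohort bookkeeping.

    Counts PASS/FAIL verdicts, tallies finding codes, and summarizes the
    gating-criteria body pass rates (median by the standard even/odd rule,
    plus range).
    """
    if not reports:
        raise ValueError("at least one report is required")
    counts = {"PASS": 0, "FAIL": 0}
    tallies: dict[str, int] = {}
    rates: list[float] = []
    for r in reports:
        counts[r.verdict] += 1
        for f in r.findings:
            tallies[f.code] = tallies.get(f.code, 0) + 1
        gating = next(iter(r.gamma_pass_rates))
        body = r.clauses[0].structure
        rate = r.gamma_pass_rates[gating].get(body)
        if rate is not None:
            rates.append(rate)
    summary = {"counts": counts, "finding_tallies": tallies, "n": len(reports)}
    if rates:
        summary["body_pass_rate"] = {
            "median": float(np.median(rates)),
            "min": float(min(rates)),
            "max": float(max(rates)),
        }
    return summary
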