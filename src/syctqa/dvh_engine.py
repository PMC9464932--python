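"""Cumulative DVHs, dosimetric parameters, and plan-to-plan differencing.

The QA decision hinges on DVH parameter differences: ΔV-type parameters
(percent of volume receiving at least a dose, e.g. V5Gy or the prescription
coverage V_Dpre) are judged in %-volume, ΔD-type parameters (dose to a
volume, e.g. Dmax, Dmean, D0.5cc, D50%) in Gy. All parameters are computed
from the raw sorted voxel doses rather than from a binned curve, because the
clinical tolerances (1 Gy, 1.5 %) demand sub-bin accuracy; the binned curve
is only used for display and for the maximum point-wise gap between two
cumulative curves.

Interpolation convention for D_y% / D_ycc: volume accumulates in whole-voxel
steps down the descending sorted dose list, and the dose at an intermediate
volume is linearly interpolated between adjacent order statistics. Whole
voxels (no partial-volume weighting) may differ slightly from TPS-exported
DVHs that use fractional voxel occupancy.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .grid import VoxelGrid
from .structure_raster import StructureMask

logger = logging.getLogger(__name__)

__all__ = [
    "DVHCurve",
    "DVHMetricSpec",
    "MetricDelta",
    "compute_dvh",
    "evaluate_metric",
    "compare_plans",
    "max_pointwise_dvh_gap",
    "dvh_band_gap",
    "parse_metric",
]

DEFAULT_BIN_WIDTH = 0.01  # Gy


@dataclass
class DVHCurve:
    """Cumulative dose–volume curve of one structure.

    ``cumulative_volume[i]`` is the percentage of the structure volume
    receiving at least ``dose_edges[i]`` Gy; it starts at 100 %, never
    increases, and reaches 0 beyond the maximum dose.
    """

    structure_name: str
    dose_edges: np.ndarray  # Gy, uniform
    cumulative_volume: np.ndarray  # % of total volume
    total_volume: float  # cc

    @property
    def absolute_volume(self) -> np.ndarray:
        """Cumulative volume in cc."""
        return self.cumulative_volume / 100.0 * self.total_volume


@dataclass(frozen=True)
class DVHMetricSpec:
    """A parsed dosimetric-parameter request.

    kind ∈ {"Dmax", "Dmean", "D_percent", "D_volume", "V_dose", "V_Dpre"};
    ``argument`` is y (% or cc) for D-type and x (Gy) for V_dose;
    ``prescription_dose`` (Gy) is required for V_Dpre.
    """

    kind: str
    argument: Optional[float] = None
    prescription_dose: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in {"Dmax", "Dmean", "D_percent", "D_volume", "V_dose", "V_Dpre"}:
            raise ValueError(f"unknown metric kind '{self.kind}'")
        if self.kind in {"D_percent", "D_volume", "V_dose"}:
            if self.argument is None or self.argument <= 0:
                raise ValueError(f"{self.kind} requires a positive argument")
            if self.kind == "D_percent" and self.argument > 100:
                raise ValueError("D_y% argument must be ≤ 100")
        if self.kind == "V_Dpre" and (
            self.prescription_dose is None or self.prescription_dose <= 0
        ):
            raise ValueError("V_Dpre requires a positive prescription dose")

    @property
    def unit(self) -> str:
        """Gy for D-type parameters, % for V-type parameters."""
        return "Gy" if self.kind in {"Dmax", "Dmean", "D_percent", "D_volume"} else "%"

    @property
    def label(self) -> str:
        if self.kind == "Dmax":
            return "Dmax"
        if self.kind == "Dmean":
            return "Dmean"
        if self.kind == "D_percent":
            return f"D{self.argument:g}%"
        if self.kind == "D_volume":
            return f"D{self.argument:g}cc"
        if self.kind == "V_dose":
            return f"V{self.argument:g}Gy"
        return f"VDpre@{self.prescription_dose:g}Gy"


_METRIC_RE = re.compile(
    r"^(?:"
    r"(?P<dmax>Dmax)|(?P<dmean>Dmean)"
    r"|D(?P<dpct>[\d.]+)%"
    r"|D(?P<dcc>[\d.]+)cc"
    r"|V(?P<vgy>[\d.]+)Gy"
    r"|VDpre(?:@(?P<pre>[\d.]+)Gy)?"
    r")$",
    re.IGNORECASE,
)


def parse_metric(text: str, prescription_dose: Optional[float] = None) -> DVHMetricSpec:
    """Parse a metric string like ``"D0.5cc"``, ``"V5Gy"``, ``"D50%"``,
    ``"Dmax"``, ``"Dmean"`` or ``"VDpre@25Gy"`` into a spec.

    A bare ``"VDpre"`` takes the prescription dose from the second argument.
    """
    m = _METRIC_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse DVH metric '{text}'")
    if m.group("dmax"):
        return DVHMetricSpec("Dmax")
    if m.group("dmean"):
        return DVHMetricSpec("Dmean")
    if m.group("dpct"):
        return DVHMetricSpec("D_percent", float(m.group("dpct")))
    if m.group("dcc"):
        return DVHMetricSpec("D_volume", float(m.group("dcc")))
    if m.group("vgy"):
        return DVHMetricSpec("V_dose", float(m.group("vgy")))
    pre = float(m.group("pre")) if m.group("pre") else prescription_dose
    return DVHMetricSpec("V_Dpre", prescription_dose=pre)


@dataclass
class MetricDelta:
    """Absolute difference of one parameter between reference and evaluated plan."""

    structure_name: str
    metric: DVHMetricSpec
    ref_value: float
    eval_value: float

    @property
    def delta(self) -> float:
        return abs(self.ref_value - self.eval_value)

    @property
    def unit(self) -> str:
        return self.metric.unit


# ---------------------------------------------------------------------------


def _masked_doses(dose: VoxelGrid, mask: StructureMask) -> np.ndarray:
    if mask.mask.shape != dose.shape:
        raise ValueError("dose and mask geometries differ; resample first")
    if not mask.mask.any():
        raise ValueError(f"empty mask for structure '{mask.name}'")
    return np.asarray(dose.values, dtype=np.float64)[mask.mask]


def compute_dvh(
    dose: VoxelGrid, mask: StructureMask, bin_width: float = DEFAULT_BIN_WIDTH
) -> DVHCurve:
    """Cumulative DVH of ``mask`` on ``dose`` with uniform bins from 0."""
    d = _masked_doses(dose, mask)
    n_bins = int(np.ceil((d.max() + bin_width) / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(d, bins=edges)
    # volume receiving >= edge e = voxels in bins at or above e
    at_least = np.concatenate([np.cumsum(counts[::-1])[::-1], [0]])
    cum = 100.0 * at_least / d.size
    return DVHCurve(
        structure_name=mask.name,
        dose_edges=edges,
        cumulative_volume=cum,
        total_volume=d.size * mask.voxel_volume,
    )


def _dose_at_volume(d_sorted_desc: np.ndarray, volume_cc: float, voxel_volume: float) -> float:
    """Largest dose d such that the volume receiving ≥ d is ≥ volume_cc.

    Linear interpolation between adjacent order statistics; volume
    accumulates in whole-voxel steps (k voxels → k·v cc at the k-th
    order statistic).
    """
    n = d_sorted_desc.size
    total = n * voxel_volume
    if volume_cc > total + 1e-12:
        raise ValueError(
            f"requested volume {volume_cc:g} cc exceeds structure volume {total:g} cc"
        )
    cum = voxel_volume * np.arange(1, n + 1)
    return float(np.interp(volume_cc, cum, d_sorted_desc))


def evaluate_metric(
    dose: VoxelGrid, mask: StructureMask, spec: DVHMetricSpec
) -> float:
    """Evaluate one dosimetric parameter from raw masked voxel doses.

    * Dmax / Dmean — max / arithmetic mean of voxel doses (Gy);
    * D_y% / D_ycc — minimum dose to the hottest y % / y cc (Gy), linearly
      interpolated between sorted voxel doses;
    * V_xGy — % of the structure volume receiving ≥ x Gy;
    * V_Dpre — V at the prescription dose (%).
    """
    d = _masked_doses(dose, mask)
    if spec.kind == "Dmax":
        return float(d.max())
    if spec.kind == "Dmean":
        return float(d.mean())
    ds = np.sort(d)[::-1]
    if spec.kind == "D_percent":
        target_cc = spec.argument / 100.0 * d.size * mask.voxel_volume
        return _dose_at_volume(ds, target_cc, mask.voxel_volume)
    if spec.kind == "D_volume":
        return _dose_at_volume(ds, spec.argument, mask.voxel_volume)
    threshold = spec.argument if spec.kind == "V_dose" else spec.prescription_dose
    return float(100.0 * np.count_nonzero(d >= threshold) / d.size)


def max_pointwise_dvh_gap(
    ref_dose: VoxelGrid,
    eval_dose: VoxelGrid,
    mask: StructureMask,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> float:
    """Maximum vertical distance (%-volume) between the two cumulative DVH
    curves of one structure on a shared dose axis.

    This realizes the "dose difference in any point of the DVH" agreement
    check in its %-volume reading.
    """
    ref = _masked_doses(ref_dose, mask)
    ev = _masked_doses(eval_dose, mask)
    top = max(ref.max(), ev.max()) + bin_width
    edges = np.arange(int(np.ceil(top / bin_width)) + 2) * bin_width
    cum_ref = _cumulative_at(ref, edges)
    cum_ev = _cumulative_at(ev, edges)
    return float(np.abs(cum_ref - cum_ev).max())


def _cumulative_at(doses: np.ndarray, edges: np.ndarray) -> np.ndarray:
    counts, _ = np.histogram(doses, bins=edges)
    at_least = np.concatenate([np.cumsum(counts[::-1])[::-1], [0]])
    return 100.0 * at_least / doses.size


def dvh_band_gap(
    ref_dose: VoxelGrid,
    eval_dose: VoxelGrid,
    mask: StructureMask,
    dose_window: float = 1.0,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> float:
    """%-volume disagreement of two DVH curves allowing a dose-axis window.

    A point of one cumulative curve agrees with the other curve when the
    other passes within ``dose_window`` Gy of it at less than the returned
    %-volume distance; the result is the worst such distance over all points
    of both curves. With ``dose_window=0`` this reduces to the plain maximum
    vertical gap. This realizes an "agrees within x %-volume or y Gy" DVH
    rule: a steep-curve region where the curves are horizontally close does
    not inflate the disagreement.
    """
    ref = _masked_doses(ref_dose, mask)
    ev = _masked_doses(eval_dose, mask)
    top = max(ref.max(), ev.max()) + dose_window + bin_width
    edges = np.arange(int(np.ceil(top / bin_width)) + 2) * bin_width
    cum_ref = _cumulative_at(ref, edges)
    cum_ev = _cumulative_at(ev, edges)
    w = int(np.floor((dose_window + 1e-12) / bin_width))
    return max(_window_gap(cum_ref, cum_ev, w), _window_gap(cum_ev, cum_ref, w))


def _window_gap(a: np.ndarray, b: np.ndarray, w: int) -> float:
    """max over i of min over |j−i|≤w of |b[j] − a[i]| for non-increasing b."""
    if w == 0:
        return float(np.abs(a - b).max())
    n = a.size
    idx = np.arange(n)
    hi = b[np.maximum(idx - w, 0)]  # b is non-increasing: window max is at the left edge
    lo = b[np.minimum(idx + w, n - 1)]
    below = np.clip(lo - a, 0, None)
    above = np.clip(a - hi, 0, None)
    return float(np.maximum(below, above).max())


def compare_plans(
    ref_dose: VoxelGrid,
    eval_dose: VoxelGrid,
    masks: Sequence[StructureMask],
    metric_table: dict[str, Sequence[Union[str, DVHMetricSpec]]],
    prescription_dose: Optional[float] = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> tuple[list[MetricDelta], dict[str, float]]:
    """Difference two plans structure-by-structure.

    ``metric_table`` maps structure names to metric strings (or specs). A
    structure present in ``masks`` but missing from the table is skipped
    with a warning. Returns the per-metric deltas and the per-structure
    maximum point-wise DVH gap in %-volume.
    """
    by_name = {m.name: m for m in masks}
    deltas: list[MetricDelta] = []
    gaps: dict[str, float] = {}
    for m in masks:
        if m.name not in metric_table:
            logger.warning("structure '%s' has no metric table entry; skipped", m.name)
            continue
        specs = [
            s if isinstance(s, DVHMetricSpec) else parse_metric(s, prescription_dose)
            for s in metric_table[m.name]
        ]
        for spec in specs:
            deltas.append(
                MetricDelta(
                    structure_name=m.name,
                    metric=spec,
                    ref_value=evaluate_metric(ref_dose, m, spec),
                    eval_value=evaluate_metric(eval_dose, m, spec),
                )
            )
        gaps[m.name] = max_pointwise_dvh_gap(ref_dose, eval_dose, m, bin_width)
    return deltas, gaps
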