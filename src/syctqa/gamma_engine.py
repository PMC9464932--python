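"""3D global gamma analysis between two dose distributions.

The gamma index at a reference voxel r is

    γ(r) = min over evaluated positions e of
           sqrt( |e − r|² / δ²  +  (D_eval(e) − D_ref(r))² / ΔD² )

with δ the distance-to-agreement criterion (mm) and ΔD the dose criterion as
a fraction of the normalization dose (global: the reference maximum). A
point agrees when γ < 1; the pass rate of a region is the percentage of its
included voxels with γ < 1. Reference voxels below the low-dose cutoff are
excluded from the analysis.

The minimization searches the evaluated dose, trilinearly interpolated on a
regular lattice of offsets (step ``interpolation_step × δ``) within a sphere
of radius ``search_radius_factor × δ``. Offsets are visited in order of
increasing distance, so a voxel whose running minimum is already below the
distance term of all remaining offsets can stop early; this prunes the vast
majority of work wherever the two doses agree, without changing the result:
the engine is exhaustive over the same lattice a brute-force search would
visit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
from scipy import ndimage

from .grid import VoxelGrid
from .structure_raster import StructureMask

logger = logging.getLogger(__name__)

__all__ = ["GammaCriteria", "GammaResult", "gamma_index", "pass_rate"]

#: point budget per vectorized batch (offsets × active voxels)
_BATCH_POINTS = 4_000_000


@dataclass(frozen=True)
class GammaCriteria:
    """Criteria and numerical settings of one gamma analysis.

    dose_criterion and low_dose_cutoff are percentages of the normalization
    dose; ``normalization`` is ``"global-max"`` (the default), ``"local"``
    (dose difference as a percentage of each reference voxel's own dose), or
    an explicit dose in Gy. ``search_radius_factor`` and
    ``interpolation_step`` (fraction of the DTA) trade accuracy for runtime
    and change γ only in the third decimal at their defaults.
    """

    dose_criterion: float = 3.0  # % of normalization dose
    dta: float = 3.0  # mm
    normalization: Union[str, float] = "global-max"
    low_dose_cutoff: float = 10.0  # % of normalization dose
    search_radius_factor: float = 3.0
    interpolation_step: float = 0.1

    def __post_init__(self) -> None:
        if self.dose_criterion <= 0 or self.dta <= 0:
            raise ValueError("dose criterion and DTA must be positive")
        if self.low_dose_cutoff < 0:
            raise ValueError("low dose cutoff must be ≥ 0")
        if self.search_radius_factor < 1:
            raise ValueError("search_radius_factor must be ≥ 1")
        if self.interpolation_step <= 0:
            raise ValueError("interpolation_step must be positive")
        if not (
            self.normalization in ("global-max", "local") or float(self.normalization) > 0
        ):
            raise ValueError("normalization must be 'global-max', 'local' or a positive dose")

    @property
    def label(self) -> str:
        return f"{self.dose_criterion:g}%/{self.dta:g}mm"


@dataclass
class GammaResult:
    """Per-voxel gamma field plus bookkeeping for pass-rate queries.

    ``gamma.values`` is NaN where the reference dose is below the low-dose
    cutoff (those voxels are excluded from every pass rate).
    """

    gamma: VoxelGrid
    criteria: GammaCriteria
    normalization_dose: float
    included: np.ndarray  # bool, voxels entering the analysis
    pass_rates: dict[str, Optional[float]] = field(default_factory=dict)

    @property
    def included_voxel_count(self) -> int:
        return int(self.included.sum())


def _offset_lattice(criteria: GammaCriteria) -> tuple[np.ndarray, np.ndarray]:
    """Offsets (mm, (m,3)) within the search sphere, sorted by distance."""
    h = criteria.interpolation_step * criteria.dta
    radius = criteria.search_radius_factor * criteria.dta
    n = int(np.floor(radius / h))
    axis = np.arange(-n, n + 1) * h
    oz, oy, ox = np.meshgrid(axis, axis, axis, indexing="ij")
    offsets = np.column_stack([oz.ravel(), oy.ravel(), ox.ravel()])
    dist = np.linalg.norm(offsets, axis=1)
    keep = dist <= radius + 1e-12
    offsets, dist = offsets[keep], dist[keep]
    order = np.argsort(dist, kind="stable")
    return offsets[order], dist[order]


def gamma_index(
    ref: VoxelGrid,
    eval_dose: VoxelGrid,
    criteria: GammaCriteria = GammaCriteria(),
    region: Optional[np.ndarray] = None,
) -> GammaResult:
    """Compute the 3D global gamma field of ``eval_dose`` against ``ref``.

    Both grids must be congruent (resample the evaluated grid first if
    not). ``region`` optionally restricts the analysis to a boolean mask in
    addition to the low-dose cutoff. Evaluated positions falling outside the
    evaluated grid's voxel-center hull are not searched.

    Raises ``ValueError`` when the reference dose is identically zero under
    global-max normalization.
    """
    if not ref.same_geometry(eval_dose):
        raise ValueError("reference and evaluated grids are not congruent; resample first")
    ref_vals = np.asarray(ref.values, dtype=np.float64)
    ev_vals = np.asarray(eval_dose.values, dtype=np.float64)

    local = criteria.normalization == "local"
    if criteria.normalization in ("global-max", "local"):
        norm = float(ref_vals.max())  # local mode still needs a cutoff reference
        if norm <= 0:
            raise ValueError("normalization dose is zero: reference dose has no positive values")
    else:
        norm = float(criteria.normalization)
    cutoff = criteria.low_dose_cutoff / 100.0 * norm

    included = ref_vals >= cutoff if cutoff > 0 else np.ones_like(ref_vals, dtype=bool)
    if local:
        included &= ref_vals > 0  # a local criterion is undefined at zero dose
    if region is not None:
        included &= np.asarray(region, dtype=bool)

    offsets_mm, dists = _offset_lattice(criteria)
    spacing_zyx = np.array([ref.spacing[2], ref.spacing[1], ref.spacing[0]])
    offsets_idx = offsets_mm / spacing_zyx  # fractional index offsets (k, j, i)
    dist_term = (dists / criteria.dta) ** 2

    vox_idx = np.argwhere(included).astype(np.float64)  # (n, 3) in (k, j, i)
    n_vox = vox_idx.shape[0]
    ref_in = ref_vals[included]
    dd_in = (
        criteria.dose_criterion / 100.0 * ref_in
        if local
        else np.full(n_vox, criteria.dose_criterion / 100.0 * norm)
    )
    gamma_sq = np.full(n_vox, np.inf)
    active = np.arange(n_vox)
    nz, ny, nx = ref.shape

    m = offsets_idx.shape[0]
    start = 0
    batch = 1  # start with the zero offset alone: it prunes most voxels at once
    while start < m and active.size:
        # voxels that cannot improve on the remaining (farther) offsets are done
        still = gamma_sq[active] > dist_term[start]
        active = active[still]
        if not active.size:
            break
        batch = max(1, min(m - start, batch * 4, _BATCH_POINTS // max(active.size, 1)))
        sl = slice(start, start + batch)
        off = offsets_idx[sl]
        kk = vox_idx[active, 0][None, :] + off[:, 0][:, None]  # (b, n)
        jj = vox_idx[active, 1][None, :] + off[:, 1][:, None]
        ii = vox_idx[active, 2][None, :] + off[:, 2][:, None]
        outside = (
            (kk < 0) | (kk > nz - 1) | (jj < 0) | (jj > ny - 1) | (ii < 0) | (ii > nx - 1)
        )
        sampled = ndimage.map_coordinates(
            ev_vals, [kk.ravel(), jj.ravel(), ii.ravel()], order=1, mode="nearest"
        ).reshape(kk.shape)
        cand = dist_term[sl][:, None] + ((sampled - ref_in[active][None, :]) / dd_in[active][None, :]) ** 2
        if outside.any():
            cand[outside] = np.inf
        gamma_sq[active] = np.minimum(gamma_sq[active], cand.min(axis=0))
        start += batch

    gamma_vals = np.full(ref.shape, np.nan)
    gamma_vals[included] = np.sqrt(gamma_sq)
    return GammaResult(
        gamma=ref.with_values(gamma_vals),
        criteria=criteria,
        normalization_dose=norm,
        included=included,
    )


def pass_rate(result: GammaResult, mask: Union[StructureMask, np.ndarray, None] = None) -> Optional[float]:
    """Percentage of included voxels (optionally within ``mask``) with γ < 1.

    Returns ``None`` (with a warning) when no included voxel falls inside
    the mask — an undefined rate, deliberately neither 0 nor 100.
    """
    sel = result.included.copy()
    name = "grid"
    if mask is not None:
        marr = mask.mask if isinstance(mask, StructureMask) else np.asarray(mask, dtype=bool)
        if marr.shape != sel.shape:
            raise ValueError("mask geometry differs from the gamma grid")
        sel &= marr
        name = mask.name if isinstance(mask, StructureMask) else "mask"
    n = int(sel.sum())
    if n == 0:
        logger.warning("no included voxels in %s; gamma pass rate undefined", name)
        return None
    g = result.gamma.values[sel]
    return float(100.0 * np.count_nonzero(g < 1.0) / n)
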