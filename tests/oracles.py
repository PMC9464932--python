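"""Independent reference implementations used to cross-check the package.

Deliberately written with different algorithms/libraries than the production
code: plain ray-crossing point-in-polygon, full (unpruned) gamma search on
the same offset lattice via scipy's RegularGridInterpolator, and sort-based
DVH statistics.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from syctqa.gamma_engine import GammaCriteria
from syctqa.grid import VoxelGrid


# ---------------------------------------------------------------- geometry

def point_in_polygon_evenodd(px: float, py: float, poly: np.ndarray) -> bool:
    """Classic even–odd ray-crossing test (edges toward +x)."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i][0], poly[i][1]
        x2, y2 = poly[(i + 1) % n][0], poly[(i + 1) % n][1]
        if (y1 > py) != (y2 > py):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_int:
                inside = not inside
    return inside


# ---------------------------------------------------------------- gamma

def gamma_oracle(ref: VoxelGrid, ev: VoxelGrid, crit: GammaCriteria) -> np.ndarray:
    """Exhaustive fine-grid gamma search: every offset for every voxel."""
    rv = np.asarray(ref.values, float)
    evv = np.asarray(ev.values, float)
    norm = rv.max() if crit.normalization == "global-max" else float(crit.normalization)
    dd = crit.dose_criterion / 100 * norm
    cutoff = crit.low_dose_cutoff / 100 * norm
    included = rv >= cutoff if cutoff > 0 else np.ones_like(rv, bool)

    h = crit.interpolation_step * crit.dta
    radius = crit.search_radius_factor * crit.dta
    n = int(np.floor(radius / h))
    ax = np.arange(-n, n + 1) * h
    oz, oy, ox = np.meshgrid(ax, ax, ax, indexing="ij")
    off = np.column_stack([oz.ravel(), oy.ravel(), ox.ravel()])
    dist = np.linalg.norm(off, axis=1)
    keep = dist <= radius + 1e-12
    off, dist = off[keep], dist[keep]
    spacing_zyx = np.array([ref.spacing[2], ref.spacing[1], ref.spacing[0]])
    off_idx = off / spacing_zyx

    interp = RegularGridInterpolator(
        tuple(np.arange(k) for k in rv.shape),
        evv,
        method="linear",
        bounds_error=False,
        fill_value=np.nan,
    )
    vox = np.argwhere(included).astype(float)
    ref_in = rv[included]
    gamma_sq = np.full(vox.shape[0], np.inf)
    for i in range(0, off_idx.shape[0], 400):
        o = off_idx[i : i + 400]
        d = dist[i : i + 400]
        pts = (vox[None, :, :] + o[:, None, :]).reshape(-1, 3)
        sampled = interp(pts).reshape(len(o), -1)
        cand = (d[:, None] / crit.dta) ** 2 + ((sampled - ref_in[None, :]) / dd) ** 2
        cand = np.where(np.isnan(cand), np.inf, cand)
        gamma_sq = np.minimum(gamma_sq, cand.min(axis=0))
    out = np.full(rv.shape, np.nan)
    out[included] = np.sqrt(gamma_sq)
    return out


def pass_rate_oracle(gamma_field: np.ndarray, mask: np.ndarray | None = None) -> float:
    sel = np.isfinite(gamma_field)
    if mask is not None:
        sel &= mask
    return 100.0 * np.count_nonzero(gamma_field[sel] < 1.0) / sel.sum()


# ---------------------------------------------------------------- DVH

def dvh_curve_oracle(doses: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Volume fraction (%) receiving at least each edge, by direct counting
    over the sorted dose list."""
    ds = np.sort(doses)
    n = ds.size
    out = np.empty(edges.size)
    for i, e in enumerate(edges):
        out[i] = 100.0 * (n - np.searchsorted(ds, e, side="left")) / n
    return out


def dose_at_volume_oracle(doses: np.ndarray, frac: float) -> float:
    """D at a fractional volume by explicit interpolation over descending
    order statistics (volume in whole-voxel steps)."""
    ds = np.sort(doses)[::-1]
    n = ds.size
    target = frac * n  # in voxel units
    ks = np.arange(1, n + 1, dtype=float)
    if target <= ks[0]:
        return float(ds[0])
    for i in range(1, n):
        if target <= ks[i]:
            t = (target - ks[i - 1]) / (ks[i] - ks[i - 1])
            return float(ds[i - 1] + t * (ds[i] - ds[i - 1]))
    return float(ds[-1])


def v_dose_oracle(doses: np.ndarray, threshold: float) -> float:
    return 100.0 * np.count_nonzero(doses >= threshold) / doses.size
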