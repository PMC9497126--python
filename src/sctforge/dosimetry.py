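"""Gamma-index dose comparison and absolute dose difference.

The gamma index combines a dose-difference tolerance (percent of the global
reference maximum) with a distance-to-agreement (DTA, mm): for each
reference point r above the low-dose cutoff,

    gamma(r) = min over positions p of
               sqrt( ((D_eval(p) - D_ref(r)) / dD)^2 + (|p - r| / dta)^2 )

where dD = dose_diff_pct/100 * max(D_ref). The evaluated dose is sampled by
linear interpolation on a fine lattice (DTA / interp_fraction steps) within
a search radius of ``search_radius_factor * dta``; offsets are scanned in
order of increasing radius with an early exit once no point can improve. A
point passes when gamma <= 1; the passing rate is the passing fraction of
above-cutoff points. Grids must share shape and spacing (resampling is the
caller's concern). 2-D and 3-D grids are supported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .types import DoseGrid

__all__ = ["GammaCriteria", "gamma_map", "gamma_pass_rate", "dose_difference"]


@dataclass
class GammaCriteria:
    dose_diff_pct: float
    dta_mm: float
    dose_cutoff_pct: float = 10.0
    normalization: str = "global"
    search_radius_factor: float = 3.0
    interp_fraction: int = 10

    def __post_init__(self):
        if self.dose_diff_pct <= 0 or self.dta_mm <= 0:
            raise ValueError("dose_diff_pct and dta_mm must be positive")
        if self.dose_cutoff_pct < 0:
            raise ValueError("dose_cutoff_pct must be non-negative")
        if self.normalization != "global":
            raise ValueError("only global normalization is provided")
        if self.search_radius_factor <= 0 or self.interp_fraction < 1:
            raise ValueError("invalid search parameters")


def _check_pair(ref: DoseGrid, ev: DoseGrid) -> None:
    if ref.shape != ev.shape:
        raise ValueError("dose grids must share a shape")
    if tuple(ref.spacing_mm) != tuple(ev.spacing_mm):
        raise ValueError("dose grids must share spacing")


def _offsets_mm(crit: GammaCriteria, ndim: int) -> np.ndarray:
    """All fine-lattice offsets within the search radius, sorted by radius."""
    step = crit.dta_mm / crit.interp_fraction
    radius = crit.search_radius_factor * crit.dta_mm
    kmax = int(np.floor(radius / step))
    axes = [np.arange(-kmax, kmax + 1) * step] * ndim
    grids = np.meshgrid(*axes, indexing="ij")
    offs = np.stack([g.ravel() for g in grids], axis=1)
    r = np.linalg.norm(offs, axis=1)
    keep = r <= radius + 1e-12
    offs, r = offs[keep], r[keep]
    order = np.argsort(r, kind="stable")
    return offs[order]


def _interp_shifted(values: np.ndarray, offset_px: np.ndarray):
    """Linear interpolation of `values` at every grid index + offset.

    Returns (interpolated array, validity mask); positions outside the grid
    are invalid.
    """
    idx = np.indices(values.shape).astype(np.float64)
    pos = idx + offset_px.reshape((-1,) + (1,) * values.ndim)
    valid = np.ones(values.shape, dtype=bool)
    for d in range(values.ndim):
        valid &= (pos[d] >= 0) & (pos[d] <= values.shape[d] - 1)
    lo = np.floor(pos).astype(int)
    frac = pos - lo
    for d in range(values.ndim):
        np.clip(lo[d], 0, values.shape[d] - 2, out=lo[d])
        frac[d] = pos[d] - lo[d]
    out = np.zeros(values.shape)
    for corner in itertools.product((0, 1), repeat=values.ndim):
        w = np.ones(values.shape)
        index = []
        for d, c in enumerate(corner):
            w = w * (frac[d] if c else (1.0 - frac[d]))
            index.append(lo[d] + c)
        out += w * values[tuple(index)]
    return out, valid


def gamma_map(ref: DoseGrid, ev: DoseGrid, crit: GammaCriteria) -> np.ndarray:
    """Per-point gamma values; NaN below the dose cutoff."""
    _check_pair(ref, ev)
    rv, evv = ref.values, ev.values
    dmax = rv.max()
    if dmax <= 0:
        raise ValueError("reference dose is identically zero")
    dd = crit.dose_diff_pct / 100.0 * dmax
    cutoff = crit.dose_cutoff_pct / 100.0 * dmax
    above = rv >= cutoff

    spacing = np.asarray(ref.spacing_mm, dtype=float)
    best = np.full(rv.shape, np.inf)
    for off in _offsets_mm(crit, rv.ndim):
        r_mm = float(np.linalg.norm(off))
        dist_term = (r_mm / crit.dta_mm) ** 2
        current_worst = best[above].max() if above.any() else 0.0
        if dist_term >= current_worst:
            break  # no remaining offset can improve any point
        vals, valid = _interp_shifted(evv, off / spacing)
        g2 = ((vals - rv) / dd) ** 2 + dist_term
        np.minimum(best, np.where(valid, g2, np.inf), out=best)
    gamma = np.sqrt(best)
    gamma[~above] = np.nan
    return gamma


def gamma_pass_rate(gamma: np.ndarray) -> float:
    """Fraction of evaluable (non-NaN) points with gamma <= 1."""
    finite = np.isfinite(gamma)
    if not finite.any():
        raise ValueError("no points above the dose cutoff")
    return float((gamma[finite] <= 1.0).mean())


def dose_difference(ref: DoseGrid, ev: DoseGrid, cutoff_pct: float = 10.0) -> float:
    """Mean |eval - ref| / max(ref) over points above the cutoff."""
    _check_pair(ref, ev)
    dmax = ref.values.max()
    if dmax <= 0:
        raise ValueError("reference dose is identically zero")
    mask = ref.values >= cutoff_pct / 100.0 * dmax
    if not mask.any():
        raise ValueError("no points above the dose cutoff")
    return float(np.mean(np.abs(ev.values[mask] - ref.values[mask])) / dmax)
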