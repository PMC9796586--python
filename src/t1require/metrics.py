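"""Comparison statistics for T1 maps and weighted images.

Covers the analyses used to validate retrospective T1 mapping against a
reference standard: box smoothing, ordinary least-squares regression with
Pearson's r and Lin's concordance correlation coefficient, the ±10%-band
"effective range" of a regression line, empirical CDFs with pairwise
Kolmogorov distances for multi-scanner conformity, and first-order error
propagation of a T2 misestimate into the derived T1.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage

from .containers import T1Map
from .signal_models import SpinEchoParams

ArrayOrMap = Union[np.ndarray, T1Map]


def _values_valid(x: ArrayOrMap) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(x, T1Map):
        return x.values, x.valid_mask
    arr = np.asarray(x, float)
    return arr, np.isfinite(arr) & (arr != 0)


@dataclass
class RegressionResult:
    """OLS agreement between two maps (B regressed on A)."""

    slope: float
    intercept: float
    pearson_r: float
    lins_ccc: float
    n: int


def smooth_maps(volume: ArrayOrMap, kernel: Tuple[int, int, int]) -> ArrayOrMap:
    """Normalized box smoothing restricted to valid voxels.

    The uniform kernel is renormalized wherever it overlaps edges or
    invalid voxels, so constants are preserved and invalid neighbours do
    not dilute the average.  A T1Map input returns a T1Map with the same
    validity mask.
    """
    kernel = tuple(int(k) for k in kernel)
    if any(k < 1 for k in kernel):
        raise ValueError(f"kernel dims must be >= 1, got {kernel}")
    values, valid = _values_valid(volume)
    w = valid.astype(float)
    box = np.ones(kernel)
    num = ndimage.convolve(values * w, box, mode="constant", cval=0.0)
    den = ndimage.convolve(w, box, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    out = np.where(valid, out, 0.0)
    if isinstance(volume, T1Map):
        return T1Map(out, valid, method=volume.method,
                     meta={**volume.meta, "smoothed": kernel},
                     affine=volume.affine)
    return out


def lins_ccc(a: np.ndarray, b: np.ndarray, population: bool = True) -> float:
    """Lin's concordance correlation coefficient.

    CCC = 2·cov(a,b) / (var a + var b + (mean a − mean b)²), with
    population (1/n) moments by default per Lin's definition; set
    ``population=False`` for sample (1/(n−1)) moments.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    ddof = 0 if population else 1
    cov = np.cov(a, b, ddof=ddof)[0, 1]
    return float(
        2 * cov / (a.var(ddof=ddof) + b.var(ddof=ddof) + (a.mean() - b.mean()) ** 2)
    )


def compare_maps(
    map_a: ArrayOrMap, map_b: ArrayOrMap, min_overlap: int = 10
) -> RegressionResult:
    """Regress map B on map A over jointly valid voxels.

    Returns the OLS slope/intercept, Pearson's r and Lin's CCC.  By
    convention A is the reference and B the map under evaluation.
    """
    va, ma = _values_valid(map_a)
    vb, mb = _values_valid(map_b)
    if va.shape != vb.shape:
        raise ValueError(f"map grids differ: {va.shape} vs {vb.shape}")
    both = ma & mb
    n = int(both.sum())
    if n < min_overlap:
        raise ValueError(f"only {n} jointly valid voxels (< {min_overlap})")
    a = va[both]
    b = vb[both]
    slope, intercept = np.polyfit(a, b, 1)
    r = float(np.corrcoef(a, b)[0, 1])
    return RegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        pearson_r=r,
        lins_ccc=lins_ccc(a, b),
        n=n,
    )


def effective_range(
    slope: float,
    intercept: float,
    pct: float = 0.10,
    upper_limit: float = 3000.0,
) -> Optional[Tuple[float, float]]:
    """T1 interval where a regression line stays within ±pct of identity.

    Solves (1−pct)·x <= slope·x + intercept <= (1+pct)·x on (0, upper_limit]
    from the two line intersections.  Returns (lo, hi) with lo = 0 meaning
    the band holds from arbitrarily small T1, or None if empty.
    """
    if not 0 < slope < 2:
        raise ValueError(f"slope must lie in (0, 2), got {slope}")
    if not 0 < pct < 1:
        raise ValueError(f"pct must lie in (0, 1), got {pct}")
    lo, hi = 0.0, float(upper_limit)

    c_up = (1 + pct) - slope  # slope·x + b <= (1+pct)x  ⇔  b <= c_up·x
    if c_up > 0:
        lo = max(lo, intercept / c_up)
    elif intercept > 0:
        return None
    elif c_up < 0:  # intercept <= 0: x <= b/c_up (positive bound)
        hi = min(hi, intercept / c_up)

    c_dn = slope - (1 - pct)  # (1−pct)x <= slope·x + b  ⇔  −b <= c_dn·x
    if c_dn > 0:
        if intercept < 0:
            lo = max(lo, -intercept / c_dn)
    elif c_dn < 0:
        if intercept < 0:
            return None
        hi = min(hi, intercept / -c_dn)
    elif intercept < 0:
        return None

    if lo >= hi:
        return None
    return (lo, hi)


def cdf_curves(
    maps_or_images: Sequence[ArrayOrMap],
    grid: Optional[np.ndarray] = None,
    n_grid: int = 2048,
) -> Tuple[np.ndarray, List[np.ndarray], np.ndarray]:
    """Empirical CDFs of valid voxels on a common grid + pairwise distances.

    Returns (grid, cdfs, D) where D[i, j] is the maximum vertical distance
    (Kolmogorov statistic) between curves i and j on the grid.
    """
    samples = []
    for x in maps_or_images:
        values, valid = _values_valid(x)
        v = values[valid]
        if v.size == 0:
            raise ValueError("an input has no valid voxels")
        samples.append(np.sort(v))
    if grid is None:
        lo = min(s[0] for s in samples)
        hi = max(s[-1] for s in samples)
        grid = np.linspace(lo, hi, n_grid)
    grid = np.asarray(grid, float)
    cdfs = [np.searchsorted(s, grid, side="right") / s.size for s in samples]
    m = len(cdfs)
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d = float(np.abs(cdfs[i] - cdfs[j]).max())
            dist[i, j] = dist[j, i] = d
    return grid, cdfs, dist


# ---------------------------------------------------------------------------
# error propagation (spin echo)
# ---------------------------------------------------------------------------

def se_signal_sensitivity_t1(
    t1: float, dt1: float, params: SpinEchoParams
) -> float:
    """Relative spin-echo signal change from a T1 misestimate dT1:
    δS/S = TR·δT1 / (T1²·(e^{TR/T1} − 1))."""
    if t1 <= 0:
        raise ValueError("T1 must be positive")
    return params.tr * dt1 / (t1 ** 2 * (np.exp(params.tr / t1) - 1.0))


def se_signal_sensitivity_t2(
    t2: float, dt2: float, params: SpinEchoParams
) -> float:
    """Relative spin-echo signal change from a T2 misestimate dT2:
    δS/S = TE·δT2 / T2²."""
    if t2 <= 0:
        raise ValueError("T2 must be positive")
    return params.te * dt2 / t2 ** 2


def t1_uncertainty_from_t2(
    t1: float, t2: float, dt2: float, params: SpinEchoParams
) -> float:
    """Relative T1 uncertainty induced by a T2 reference error dT2.

    Equating the signal perturbations from T1 and T2 gives
    δT1/T1 = TE·δT2·T1·(e^{TR/T1} − 1) / (TR·T2²) — the first-order cost,
    in the derived T1, of using a literature T2 that misses the voxel's
    true T2 by dT2.  Returned as a fraction.
    """
    if min(t1, t2) <= 0 or dt2 < 0:
        raise ValueError("T1, T2 must be positive and dT2 >= 0")
    return float(
        params.te * dt2 * t1 * (np.exp(params.tr / t1) - 1.0)
        / (params.tr * t2 ** 2)
    )
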