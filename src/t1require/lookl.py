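"""Reference-standard Look-Locker multi-TI T1 mapping.

Each voxel's inversion-recovery samples are fitted to the three-parameter
model S(TI) = A − B·e^{−TI/T1*} and corrected to true T1 = T1*(B/A − 1).
The fit uses variable projection: for any trial T1* the optimal (A, B) are
a closed-form linear least-squares solution, so the nonlinear problem
reduces to a 1D search over T1* — done on a coarse logarithmic grid and
refined by a vectorized ternary search, which fits whole volumes at once.

Magnitude inversion-recovery data lose the sign of the early samples; when
``magnitude`` is set, polarity is restored by brute force: every candidate
sign-flip index (the first j time-ordered samples negated) is fitted and
the minimum-residual fit kept.
"""
from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

from .containers import T1Map, VolumeImage
from .signal_models import LookLockerFit

_TAU_BOUNDS = (5.0, 30000.0)  # ms; generous bracket for apparent T1*
_GRID_POINTS = 64
_REFINE_ITERS = 80


def _linear_solve(
    tau: np.ndarray, signals: np.ndarray, tis: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal (A, B) and residual sum of squares for per-voxel tau.

    signals: (V, K); tau: (V,); tis: (K,).  Model S = A − B·e^{−TI/tau}.
    """
    e = np.exp(-tis[None, :] / tau[:, None])
    k = tis.size
    se = e.sum(1)
    see = (e * e).sum(1)
    ss = signals.sum(1)
    sse = (signals * e).sum(1)
    det = k * see - se * se
    det = np.where(np.abs(det) < 1e-300, np.nan, det)
    b = (ss * se - k * sse) / det
    a = (ss + b * se) / k
    resid = ((signals - (a[:, None] - b[:, None] * e)) ** 2).sum(1)
    return a, b, resid


def _fit_tau(signals: np.ndarray, tis: np.ndarray) -> Tuple[np.ndarray, ...]:
    """Variable-projection fit over a log grid + ternary refinement.

    Returns (a, b, tau, residual) arrays over voxels.
    """
    log_grid = np.linspace(*np.log(_TAU_BOUNDS), _GRID_POINTS)
    rss = np.empty((_GRID_POINTS, signals.shape[0]))
    for i, lg in enumerate(log_grid):
        tau = np.full(signals.shape[0], np.exp(lg))
        rss[i] = _linear_solve(tau, signals, tis)[2]
    best = np.nanargmin(rss, axis=0)
    lo = log_grid[np.maximum(best - 1, 0)]
    hi = log_grid[np.minimum(best + 1, _GRID_POINTS - 1)]
    for _ in range(_REFINE_ITERS):
        m1 = lo + (hi - lo) / 3
        m2 = hi - (hi - lo) / 3
        r1 = _linear_solve(np.exp(m1), signals, tis)[2]
        r2 = _linear_solve(np.exp(m2), signals, tis)[2]
        take_left = r1 <= r2
        hi = np.where(take_left, m2, hi)
        lo = np.where(take_left, lo, m1)
    tau = np.exp((lo + hi) / 2)
    a, b, resid = _linear_solve(tau, signals, tis)
    return a, b, tau, resid


def _fit_block(
    signals: np.ndarray, tis: np.ndarray, magnitude: bool
) -> Tuple[np.ndarray, ...]:
    """Fit a (V, K) block, optionally restoring polarity of magnitude data."""
    order = np.argsort(tis)
    tis_sorted = tis[order]
    sig_sorted = signals[:, order]
    if not magnitude:
        return _fit_tau(sig_sorted, tis_sorted)
    best: Optional[Tuple[np.ndarray, ...]] = None
    for flip in range(tis.size + 1):
        s = sig_sorted.copy()
        s[:, :flip] *= -1.0  # earliest samples were negative pre-magnitude
        a, b, tau, resid = _fit_tau(s, tis_sorted)
        if best is None:
            best = (a, b, tau, resid)
        else:
            better = resid < best[3]
            best = tuple(np.where(better, new, old)
                         for new, old in zip((a, b, tau, resid), best))
    return best


def fit_looklocker_voxel(
    signals: Sequence[float], tis: Sequence[float], magnitude: bool = False
) -> LookLockerFit:
    """Fit one voxel's multi-TI samples; returns the best LookLockerFit."""
    tis = np.asarray(tis, float)
    signals = np.asarray(signals, float)
    if tis.size < 3 or np.unique(tis).size < 3:
        raise ValueError("need at least 3 distinct inversion times")
    if signals.shape != tis.shape:
        raise ValueError("signals and TIs must have equal length")
    if not np.all(np.isfinite(signals)):
        raise ValueError("signals must be finite")
    a, b, tau, resid = _fit_block(signals[None, :], tis, magnitude)
    a, b, tau, resid = float(a[0]), float(b[0]), float(tau[0]), float(resid[0])
    valid = np.isfinite(resid) and tau > 0 and a != 0 and b / a > 1
    if not valid:
        return LookLockerFit(a=a, b=b, t1star=max(tau, 1e-6), residual=resid,
                             valid=False)
    return LookLockerFit(a=a, b=b, t1star=tau, residual=resid, valid=True)


def lookl_map(
    images: Sequence[VolumeImage],
    tis: Sequence[float],
    mask: Optional[np.ndarray] = None,
    magnitude: bool = False,
) -> T1Map:
    """Voxelwise Look-Locker fit + correction over a multi-TI series.

    Voxels are invalid where the fit degenerates (e.g. constant signal) or
    B/A <= 1 makes the correction non-physical.
    """
    tis = np.asarray(tis, float)
    if len(images) != tis.size:
        raise ValueError(
            f"{len(images)} images but {tis.size} inversion times"
        )
    if tis.size < 3:
        raise ValueError("need at least 3 inversion times")
    shape = images[0].shape
    for img in images[1:]:
        if img.shape != shape:
            raise ValueError("all TI images must share one grid")
    data = np.stack([img.data for img in images], axis=-1)  # (x,y,z,K)
    if mask is None:
        mask = np.abs(data).max(axis=-1) > 0
    mask = np.asarray(mask, bool)

    flat = data[mask]  # (V, K)
    values = np.zeros(shape)
    valid = np.zeros(shape, bool)
    if flat.shape[0]:
        a, b, tau, resid = _fit_block(flat, tis, magnitude)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(a != 0, b / np.where(a == 0, 1.0, a), -np.inf)
        ok = np.isfinite(resid) & np.isfinite(ratio) & (ratio > 1) & (tau > 0)
        t1 = np.where(ok, tau * (ratio - 1.0), 0.0)
        values[mask] = t1
        vm = np.zeros(shape, bool)
        vm[mask] = ok
        valid = vm
    meta = {"tis": tis.tolist(), "magnitude": magnitude,
            "n_valid_voxels": int(valid.sum())}
    return T1Map(values, valid, method="LOOK-LOCKER", meta=meta,
                 affine=images[0].affine)
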