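"""MPRAGE T1-REQUIRE pipeline.

The MPRAGE steady-state signal has no simple analytic inverse, so the
pipeline fits the equilibrium-magnetization scale M0 to the whole-volume
reference-tissue means (the model is linear in M0, giving a closed-form
least-squares solution), tabulates the forward model on a dense T1 grid,
and inverts each in-mask voxel by interpolating the monotone lookup table.
Unlike the spin-echo pipeline there is no per-slice requirement: one fit
serves the whole volume.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .containers import T1Map, TissueMasks, VolumeImage
from .require_se import build_brain_mask
from .signal_models import MPRAGEParams, ReferenceParams, mprage_signal

logger = logging.getLogger(__name__)


@dataclass
class SignalLUT:
    """Monotone table pairing a T1 grid with model MPRAGE signals."""

    t1_grid: np.ndarray
    signals: np.ndarray
    m0: float
    params: MPRAGEParams

    def __post_init__(self) -> None:
        self.t1_grid = np.asarray(self.t1_grid, float)
        self.signals = np.asarray(self.signals, float)
        if self.t1_grid.ndim != 1 or self.t1_grid.size < 2:
            raise ValueError("t1_grid must be a 1D grid with >= 2 points")
        if np.any(np.diff(self.t1_grid) <= 0):
            raise ValueError("t1_grid must be strictly ascending")
        d = np.diff(self.signals)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("LUT signals must be strictly monotone")

    @property
    def step(self) -> float:
        return float(np.diff(self.t1_grid).max())

    def invert(self, signals: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Piecewise-linear inverse lookup; out-of-range signals invalid."""
        s = np.asarray(signals, float)
        lo, hi = self.signals.min(), self.signals.max()
        valid = (s >= lo) & (s <= hi)
        if self.signals[0] > self.signals[-1]:  # decreasing in T1
            xp, fp = self.signals[::-1], self.t1_grid[::-1]
        else:
            xp, fp = self.signals, self.t1_grid
        t1 = np.interp(np.clip(s, lo, hi), xp, fp)
        return np.where(valid, t1, 0.0), valid


def fit_m0(
    tissue_means: Sequence[Tuple[float, float]], params: MPRAGEParams
) -> Tuple[float, float]:
    """Least-squares M0 from (mean signal, reference T1) pairs.

    The steady-state signal is proportional to M0, so the minimizer of
    Σ (mean_t − M0·g_t)² with g_t = signal at unit M0 is the closed form
    M0 = Σ mean_t·g_t / Σ g_t².  Returns (m0, residual sum of squares).
    """
    pairs = [(float(s), float(t1)) for s, t1 in tissue_means]
    if any(t1 <= 0 for _, t1 in pairs):
        raise ValueError("reference T1s must be positive")
    s = np.array([p[0] for p in pairs])
    g = np.array([mprage_signal(p[1], 1.0, params) for p in pairs])
    denom = float((g * g).sum())
    if denom < 1e-30:
        raise ValueError("degenerate model signals: cannot fit M0")
    m0 = float((s * g).sum() / denom)
    residual = float(((s - m0 * g) ** 2).sum())
    return m0, residual


def _largest_monotone_run(signals: np.ndarray) -> Tuple[int, int]:
    """Index range [i, j] of the longest strictly monotone run."""
    d = np.sign(np.diff(signals))
    best = (0, 1)
    start = 0
    for i in range(1, d.size):
        if d[i] != d[start] or d[i] == 0:
            if i - start > best[1] - best[0]:
                best = (start, i)
            start = i
    if d.size - start > best[1] - best[0]:
        best = (start, d.size)
    return best[0], best[1]


def build_lut(
    m0: float,
    params: MPRAGEParams,
    t1_range: Tuple[float, float] = (1.0, 5000.0),
    step: float = 1.0,
    required_range: Tuple[float, float] = (400.0, 4000.0),
) -> SignalLUT:
    """Tabulate the MPRAGE forward model on a dense T1 grid.

    If the model is not monotone over the full range (possible near signal
    nulls at long inversion times), the table is restricted to the largest
    strictly monotone subrange; it must still cover ``required_range`` or a
    ValueError names the largest monotone subrange found.
    """
    lo, hi = t1_range
    if not (0 < lo < hi and step > 0):
        raise ValueError(f"bad T1 range {t1_range} / step {step}")
    grid = np.arange(lo, hi + step / 2, step)
    signals = mprage_signal(grid, m0, params)
    d = np.diff(signals)
    if not (np.all(d > 0) or np.all(d < 0)):
        i, j = _largest_monotone_run(signals)
        sub = (float(grid[i]), float(grid[j]))
        if sub[0] > required_range[0] or sub[1] < required_range[1]:
            raise ValueError(
                "MPRAGE signal is not monotone over "
                f"{t1_range} ms; largest monotone subrange is {sub} ms, "
                f"which does not cover {required_range}"
            )
        logger.warning("LUT restricted to monotone subrange %s ms", sub)
        grid, signals = grid[i : j + 1], signals[i : j + 1]
    return SignalLUT(t1_grid=grid, signals=signals, m0=m0, params=params)


def invert_via_lut(
    image: VolumeImage, lut: SignalLUT, mask: np.ndarray
) -> T1Map:
    """Convert an MPRAGE volume to a T1 map through the lookup table."""
    mask = np.asarray(mask, bool)
    if mask.shape != image.shape:
        raise ValueError(f"mask grid {mask.shape} != image grid {image.shape}")
    t1, ok = lut.invert(image.data)
    valid = mask & ok
    values = np.where(valid, t1, 0.0)
    frac = float((mask & ~ok).sum()) / max(int(mask.sum()), 1)
    if frac > 0.01:
        logger.warning("%.1f%% of in-mask voxels outside the LUT range", 100 * frac)
    meta = {"m0": lut.m0, "lut_step": lut.step,
            "t1_range": (float(lut.t1_grid[0]), float(lut.t1_grid[-1]))}
    return T1Map(values, valid, method="MPRAGE-REQUIRE", meta=meta,
                 affine=image.affine)


def require_mprage_pipeline(
    image: VolumeImage,
    masks: TissueMasks,
    params: MPRAGEParams,
    refs: Optional[ReferenceParams] = None,
    *,
    t1_range: Tuple[float, float] = (1.0, 5000.0),
    step: float = 1.0,
) -> Tuple[T1Map, Dict]:
    """Full MPRAGE conversion: mask → whole-volume tissue means → M0 fit →
    lookup table → voxelwise inversion.  Gain-invariant because M0 rescales
    with the image."""
    refs = refs or ReferenceParams()
    if image.shape != masks.shape:
        raise ValueError(f"image grid {image.shape} != mask grid {masks.shape}")
    brain_mask = build_brain_mask(masks)
    hard = masks.hard_masks()

    pairs = []
    means = {}
    for tissue, ref in refs.tissues().items():
        m = getattr(hard, tissue)
        if not m.any():
            raise ValueError(f"no voxels for reference tissue '{tissue}'")
        mean = float(image.data[m].mean())
        means[tissue] = mean
        pairs.append((mean, ref.t1))

    m0, residual = fit_m0(pairs, params)
    logger.info("M0 fit: %.6g (residual %.3g)", m0, residual)
    lut = build_lut(m0, params, t1_range=t1_range, step=step)
    t1_map = invert_via_lut(image, lut, brain_mask)
    report = {
        "m0": m0,
        "residual": residual,
        "tissue_means": means,
        "lut": {
            "t1_min": float(lut.t1_grid[0]),
            "t1_max": float(lut.t1_grid[-1]),
            "step": lut.step,
        },
        "n_valid_voxels": int(t1_map.valid_mask.sum()),
    }
    t1_map.meta.update(report)
    return t1_map, report
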