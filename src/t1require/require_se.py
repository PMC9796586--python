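"""Spin-echo T1-REQUIRE pipeline.

Steps: build a brain mask from the tissue segments (union + morphological
closing with hole filling), divide out the T2/ρ weighting with literature
reference values to obtain the purely T1-weighted image S_T1, then — slice
by slice along the axial direction, to absorb B0-related intensity drift —
fit the scanner gain k to the three reference-tissue means of S_T1 and
invert k·(1 − e^{−TR/T1}) analytically for every in-mask voxel.  Only
slices containing all three reference tissues can be converted; others are
flagged invalid.  Because k rescales with the image, the output T1 map is
invariant to any global intensity gain.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .containers import T1Map, TissueMasks, VolumeImage
from .signal_models import ReferenceParams, SpinEchoParams, se_invert_volume

logger = logging.getLogger(__name__)


@dataclass
class SliceFit:
    """Per-slice scanner-gain fit diagnostics."""

    slice_index: int
    k: float = 0.0
    tissue_means: Dict[str, float] = field(default_factory=dict)
    residual: float = float("nan")
    valid: bool = False


def build_brain_mask(masks: TissueMasks) -> np.ndarray:
    """Skull-strip mask: GM∪WM∪CSF closed morphologically with hole filling.

    One binary dilation, hole filling, then one binary erosion — so the
    result always contains the original union.
    """
    union = masks.hard_masks().union()
    if not union.any():
        raise ValueError("tissue masks are empty: cannot build a brain mask")
    mask = ndimage.binary_dilation(union)
    mask = ndimage.binary_fill_holes(mask)
    mask = ndimage.binary_erosion(mask)
    mask = ndimage.binary_fill_holes(mask)
    # closing ⊇ interior of the union; keep the union itself by construction
    return mask | union


def t2rho_correction(
    image: VolumeImage,
    masks: TissueMasks,
    refs: Optional[ReferenceParams] = None,
    params: Optional[SpinEchoParams] = None,
    sigma: float = 2.0,
    brain_mask: Optional[np.ndarray] = None,
) -> VolumeImage:
    """Divide the T2 decay and proton density out of a spin-echo image.

    Builds the voxelwise correction factor e^{TE/T2_ref}/ρ_ref from the
    per-tissue assignments, smooths it with a 2D Gaussian (σ in voxels)
    across the sagittal and coronal directions (i.e. in-plane for each
    axial slice), and multiplies the skull-stripped image, yielding the
    purely T1-weighted S_T1.  In-mask voxels without a tissue assignment
    receive the factor of the nearest assigned voxel (logged).
    """
    refs = refs or ReferenceParams()
    if params is None:
        raise ValueError("spin-echo sequence parameters are required")
    if image.shape != masks.shape:
        raise ValueError(
            f"image grid {image.shape} != mask grid {masks.shape}"
        )
    hard = masks.hard_masks()
    if brain_mask is None:
        brain_mask = build_brain_mask(masks)

    factor = np.zeros(image.shape)
    assigned = np.zeros(image.shape, bool)
    for tissue, ref in refs.tissues().items():
        m = getattr(hard, tissue)
        factor[m] = np.exp(params.te / ref.t2) / ref.rho
        assigned |= m

    missing = brain_mask & ~assigned
    if missing.any():
        logger.info(
            "t2rho_correction: %d in-mask voxels without tissue assignment; "
            "using nearest-tissue factor", int(missing.sum()),
        )
        idx = ndimage.distance_transform_edt(
            ~assigned, return_distances=False, return_indices=True
        )
        factor[missing] = factor[tuple(i[missing] for i in idx)]
        assigned |= missing

    if sigma > 0:
        weight = (brain_mask & assigned).astype(float)
        num = ndimage.gaussian_filter(factor * weight, sigma=(sigma, sigma, 0))
        den = ndimage.gaussian_filter(weight, sigma=(sigma, sigma, 0))
        with np.errstate(invalid="ignore", divide="ignore"):
            smoothed = np.where(den > 1e-12, num / np.maximum(den, 1e-300), 0.0)
        factor = np.where(brain_mask, smoothed, 0.0)

    s_t1 = np.where(brain_mask, image.data * factor, 0.0)
    return VolumeImage(s_t1, image.affine)


def fit_k(
    tissue_means: Sequence[Tuple[float, float]], tr: float
) -> Tuple[float, float]:
    """Least-squares scanner gain from (mean S_T1, reference T1) pairs.

    The model S_T1 = k·(1 − e^{−TR/T1}) is linear in its single free
    parameter, so the minimizer is the closed form
    k = Σ s_i f_i / Σ f_i² with f_i = 1 − e^{−TR/T1_i}.
    Returns (k, residual sum of squares).
    """
    pairs = [(float(s), float(t1)) for s, t1 in tissue_means]
    if any(s <= 0 or t1 <= 0 for s, t1 in pairs):
        raise ValueError("tissue means and reference T1s must be positive")
    s = np.array([p[0] for p in pairs])
    f = 1.0 - np.exp(-tr / np.array([p[1] for p in pairs]))
    k = float((s * f).sum() / (f * f).sum())
    residual = float(((s - k * f) ** 2).sum())
    return k, residual


def require_se_pipeline(
    image: VolumeImage,
    masks: TissueMasks,
    params: SpinEchoParams,
    refs: Optional[ReferenceParams] = None,
    *,
    sigma: float = 2.0,
    min_voxels: int = 50,
    clamp_max: float = 5000.0,
) -> Tuple[T1Map, List[SliceFit]]:
    """Convert a T1-weighted spin-echo volume to a T1 map, slice by slice.

    Each axial slice must contain at least ``min_voxels`` of each of
    GM/WM/CSF to be converted; the gain k is fitted per slice from the
    three reference means and every in-mask voxel is inverted analytically.
    Voxels whose corrected signal lies outside (0, k), or whose T1 exceeds
    ``clamp_max`` (or is non-positive), are flagged invalid rather than
    clamped.
    """
    refs = refs or ReferenceParams()
    brain_mask = build_brain_mask(masks)
    s_t1_img = t2rho_correction(
        image, masks, refs, params, sigma=sigma, brain_mask=brain_mask
    )
    s_t1 = s_t1_img.data
    hard = masks.hard_masks()

    values = np.zeros(image.shape)
    valid = np.zeros(image.shape, bool)
    fits: List[SliceFit] = []
    n_invalid = 0
    for z in range(image.shape[2]):
        fit = SliceFit(slice_index=z)
        fits.append(fit)
        tissue_pairs = []
        means = {}
        ok = True
        for tissue, ref in refs.tissues().items():
            m = getattr(hard, tissue)[:, :, z]
            if int(m.sum()) < min_voxels:
                ok = False
                break
            mean = float(s_t1[:, :, z][m].mean())
            means[tissue] = mean
            tissue_pairs.append((mean, ref.t1))
        if not ok or any(m <= 0 for m in means.values()):
            continue
        try:
            k, residual = fit_k(tissue_pairs, params.tr)
        except ValueError:
            continue
        fit.k, fit.residual, fit.tissue_means, fit.valid = k, residual, means, True
        logger.info("slice %d: k=%.6g residual=%.3g", z, k, residual)

        sl = brain_mask[:, :, z]
        t1_sl, ok_sl = se_invert_volume(s_t1[:, :, z], k, params.tr)
        ok_sl &= sl & (t1_sl > 0) & (t1_sl <= clamp_max)
        n_invalid += int((sl & ~ok_sl).sum())
        values[:, :, z] = np.where(ok_sl, t1_sl, 0.0)
        valid[:, :, z] = ok_sl

    if not any(f.valid for f in fits):
        raise ValueError(
            "no axial slice contains all three reference tissues "
            f"(min {min_voxels} voxels each): cannot convert"
        )
    frac = n_invalid / max(int(brain_mask.sum()), 1)
    if frac > 0.01:
        logger.warning("%.1f%% of in-mask voxels failed inversion", 100 * frac)

    meta = {
        "sequence": {"tr": params.tr, "te": params.te},
        "sigma": sigma,
        "min_voxels": min_voxels,
        "clamp_max": clamp_max,
        "n_valid_slices": sum(f.valid for f in fits),
        "n_invalid_voxels": n_invalid,
    }
    t1_map = T1Map(values, valid, method="SE-REQUIRE", meta=meta, affine=image.affine)
    return t1_map, fits
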