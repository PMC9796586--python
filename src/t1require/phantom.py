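"""Seeded synthetic digital brain phantom and forward acquisition simulator.

The phantom is a deterministic nested geometry — a CSF shell around a GM
ribbon around a WM core, with a central CSF "ventricle" — built from a
superellipsoid profile so that almost every axial slice contains all three
reference tissues (the per-slice requirement of the spin-echo pipeline).
Per-voxel T1/T2/ρ are drawn from truncated normals centred on the 3 T
literature means, with the spread scaled by a ``heterogeneity`` fraction.

Forward simulators evaluate the closed-form sequence models voxelwise and
add seeded Gaussian noise inside tissue (an optional magnitude/Rician mode
is available for the Look-Locker series).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .containers import TissueMasks, VolumeImage
from .signal_models import (
    LookLockerFit,
    MPRAGEParams,
    ReferenceParams,
    SpinEchoParams,
    looklocker_signal,
    mprage_signal,
    se_signal,
)

LABELS = {"gm": 1, "wm": 2, "csf": 3}

#: Default inversion times of the multi-TI Look-Locker protocol (ms).
DEFAULT_LL_TIS = (150.0, 400.0, 750.0, 1500.0, 3500.0)


@dataclass(frozen=True)
class ScannerPreset:
    """One scanner's MPRAGE protocol for the multi-scanner experiment.

    TR/TE/TI, slice count, in-plane FOV and 1 mm isotropic voxels follow the
    six-scanner 3 T study protocols.  Those protocols do not state the flip
    angle, recovery period or readout-train length, so all presets use
    α = 9°, Trec = 400 ms (the single-site Ingenia protocol values) and
    N = slice count rounded up to even.
    """

    name: str
    params: MPRAGEParams
    slices: int
    fov: Tuple[float, float]
    noise_sd: float = 0.02
    m0: float = 1000.0


def _preset(name, tr, te, ti, slices, fov) -> ScannerPreset:
    n = slices + slices % 2
    return ScannerPreset(
        name=name,
        params=MPRAGEParams(tr=tr, te=te, alpha=9.0, ti=ti, trec=400.0, n=n),
        slices=slices,
        fov=fov,
    )


#: The six multi-scanner MPRAGE protocols plus the single-site Ingenia
#: protocol ("ingenia-hc") used alongside the spin-echo and Look-Locker scans.
SCANNER_PRESETS: Dict[str, ScannerPreset] = {
    "discovery1": _preset("discovery1", 8.5, 3.2, 450.0, 182, (256, 256)),
    "discovery2": _preset("discovery2", 8.6, 3.2, 450.0, 174, (256, 256)),
    "architect": _preset("architect", 7.9, 3.1, 450.0, 174, (250, 256)),
    "achieva1": _preset("achieva1", 7.9, 3.5, 827.7, 160, (250, 199)),
    "achieva2": _preset("achieva2", 6.9, 3.5, 810.0, 180, (250, 225)),
    "ingenia": _preset("ingenia", 8.1, 3.7, 1010.0, 167, (240, 240)),
    "ingenia-hc": ScannerPreset(
        name="ingenia-hc",
        params=MPRAGEParams(tr=8.0, te=2.89, alpha=9.0, ti=358.0, trec=400.0, n=176),
        slices=176,
        fov=(256, 256),
    ),
}

#: Names of the six multi-scanner presets, in protocol-table order.
MULTISCANNER_PRESETS = (
    "discovery1", "discovery2", "architect", "achieva1", "achieva2", "ingenia",
)


@dataclass
class TissuePhantom:
    """Digital brain phantom: label geometry plus ground-truth parameter maps."""

    labels: np.ndarray
    t1_map: np.ndarray
    t2_map: np.ndarray
    rho_map: np.ndarray
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0
    meta: Dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def masks(self) -> TissueMasks:
        return TissueMasks(
            gm=self.labels == LABELS["gm"],
            wm=self.labels == LABELS["wm"],
            csf=self.labels == LABELS["csf"],
        )

    def tissue_mask(self, tissue: str) -> np.ndarray:
        return self.labels == LABELS[tissue]

    def complete_slices(self, min_voxels: int = 50) -> np.ndarray:
        """Boolean per axial slice: all three tissues with >= min_voxels."""
        out = np.ones(self.shape[2], bool)
        for label in LABELS.values():
            counts = (self.labels == label).sum(axis=(0, 1))
            out &= counts >= min_voxels
        return out


def _truncated_normal(
    mean: float, sigma: float, size: int, rng: np.random.Generator, nsig: float = 3.0
) -> np.ndarray:
    """Normal(mean, sigma) truncated at ±nsig·sigma (keeps T1 etc. physical)."""
    if sigma <= 0:
        return np.full(size, mean)
    return stats.truncnorm.rvs(
        -nsig, nsig, loc=mean, scale=sigma, size=size, random_state=rng
    )


def make_phantom(
    shape: Tuple[int, int, int] = (64, 64, 64),
    seed: int = 0,
    refs: Optional[ReferenceParams] = None,
    heterogeneity: float = 1.0,
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> TissuePhantom:
    """Build a deterministic nested-shell brain phantom.

    Geometry (fractions of the in-plane radius, with a superellipsoid axial
    profile): CSF shell outside 0.85, GM ribbon 0.55–0.85, WM core inside
    0.55, central CSF ventricle inside 0.14.  heterogeneity scales the
    literature σ of the per-voxel truncated-normal parameter draws
    (0 → every voxel at the tissue mean).
    """
    refs = refs or ReferenceParams()
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 32:
        raise ValueError(f"phantom shape must be >= 32 per axis, got {shape}")
    if not 0 <= heterogeneity <= 1:
        raise ValueError("heterogeneity must lie in [0, 1]")

    nx, ny, nz = shape
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    u = (x - (nx - 1) / 2) / (0.46 * nx)
    v = (y - (ny - 1) / 2) / (0.46 * ny)
    w = (z - (nz - 1) / 2) / (0.49 * nz)
    # superellipsoid axial profile: nearly cylindrical with rounded caps,
    # so the in-plane cross-section shrinks only near the top/bottom slices
    profile = np.sqrt(np.clip(1.0 - w ** 8, 0.0, None))
    r = np.sqrt(u ** 2 + v ** 2)

    labels = np.zeros(shape, dtype=np.int16)
    inside = (r <= profile) & (profile > 0)
    labels[inside & (r > 0.85 * profile)] = LABELS["csf"]
    labels[inside & (r <= 0.85 * profile) & (r > 0.55 * profile)] = LABELS["gm"]
    labels[inside & (r <= 0.55 * profile)] = LABELS["wm"]
    labels[inside & (r <= 0.14 * profile)] = LABELS["csf"]  # ventricle

    rng = np.random.default_rng(seed)
    t1 = np.zeros(shape)
    t2 = np.zeros(shape)
    rho = np.zeros(shape)
    for tissue, ref in refs.tissues().items():
        m = labels == LABELS[tissue]
        n = int(m.sum())
        t1[m] = _truncated_normal(ref.t1, heterogeneity * ref.t1_sigma, n, rng)
        t2[m] = _truncated_normal(ref.t2, heterogeneity * ref.t2_sigma, n, rng)
        rho[m] = _truncated_normal(ref.rho, heterogeneity * ref.rho_sigma, n, rng)

    return TissuePhantom(
        labels=labels,
        t1_map=t1,
        t2_map=t2,
        rho_map=rho,
        voxel_size=voxel_size,
        seed=seed,
        meta={"heterogeneity": heterogeneity},
    )


def _affine(ph: TissuePhantom) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = ph.voxel_size
    return aff


def _add_noise(
    signal: np.ndarray,
    tissue: np.ndarray,
    noise_sd: float,
    seed: int,
    magnitude: bool = False,
) -> np.ndarray:
    """Add Gaussian noise (sd = noise_sd × mean tissue |signal|) inside tissue."""
    out = signal.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sd = noise_sd * float(np.abs(signal[tissue]).mean())
        out[tissue] = out[tissue] + rng.normal(0.0, sd, size=int(tissue.sum()))
    if magnitude:
        out = np.abs(out)
    return out


def simulate_spin_echo(
    ph: TissuePhantom,
    params: SpinEchoParams,
    k: float = 1000.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> VolumeImage:
    """Forward-simulate a T1-weighted spin-echo volume of the phantom."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    tissue = ph.labels > 0
    signal = np.zeros(ph.shape)
    signal[tissue] = se_signal(
        ph.t1_map[tissue], ph.t2_map[tissue], ph.rho_map[tissue], params, k=k
    )
    return VolumeImage(_add_noise(signal, tissue, noise_sd, seed), _affine(ph))


def simulate_mprage(
    ph: TissuePhantom,
    preset: ScannerPreset,
    m0: Optional[float] = None,
    noise_sd: Optional[float] = None,
    seed: int = 0,
) -> VolumeImage:
    """Forward-simulate an MPRAGE volume at the center of k-space.

    Uses a spatially uniform M0 (the model the lookup-table pipeline
    assumes); signals are signed steady-state magnetizations.
    """
    m0 = preset.m0 if m0 is None else m0
    noise_sd = preset.noise_sd if noise_sd is None else noise_sd
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    tissue = ph.labels > 0
    signal = np.zeros(ph.shape)
    signal[tissue] = mprage_signal(ph.t1_map[tissue], m0, preset.params)
    return VolumeImage(_add_noise(signal, tissue, noise_sd, seed), _affine(ph))


def simulate_look_locker(
    ph: TissuePhantom,
    tis: Sequence[float] = DEFAULT_LL_TIS,
    a_scale: float = 1000.0,
    bover_a: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    magnitude: bool = False,
) -> List[VolumeImage]:
    """Forward-simulate a multi-TI Look-Locker series.

    Per voxel the apparent relaxation time is T1* = T1/(B/A − 1) — the
    inverse of the Look-Locker correction — so the corrected map recovers
    the ground truth.  bover_a = 2 corresponds to an ideal inversion with
    negligible readout perturbation (T1* = T1).
    """
    tis = [float(t) for t in tis]
    if len(set(tis)) < 3:
        raise ValueError("need at least 3 distinct inversion times")
    if not bover_a > 1:
        raise ValueError("B/A must exceed 1")
    tissue = ph.labels > 0
    t1star = np.zeros(ph.shape)
    t1star[tissue] = ph.t1_map[tissue] / (bover_a - 1.0)
    out = []
    for i, ti in enumerate(tis):
        signal = np.zeros(ph.shape)
        fit = LookLockerFit(a=a_scale, b=bover_a * a_scale, t1star=1.0)
        # evaluate A − B e^{−TI/T1*} with per-voxel T1*
        signal[tissue] = fit.a - fit.b * np.exp(-ti / t1star[tissue])
        signal = _add_noise(signal, tissue, noise_sd, seed + 1000 * i, magnitude)
        out.append(VolumeImage(signal, _affine(ph)))
    return out
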