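"""Closed-form MR signal models and their inverses.

Three sequences are covered:

* **Spin echo** — T1-weighted signal ``S = k·ρ·(1 − e^{−TR/T1})·e^{−TE/T2}``.
  Dividing out the T2/ρ factors with literature values leaves the purely
  T1-weighted ``S_T1 = k·(1 − e^{−TR/T1})``, which inverts analytically.
* **MPRAGE** — inversion pulse, a train of N spoiled gradient-echo readouts
  at flip angle α spaced TR apart, then a recovery period Trec; repeated to
  steady state.  The longitudinal magnetization at the center of k-space
  (readout index N/2 − 1) carries the image contrast.  T2* decay at the echo
  time is ignored; the sin α receive factor is a T1-independent scale that is
  absorbed into the fitted M0.
* **Look-Locker** — three-parameter recovery ``S(TI) = A − B·e^{−TI/T1*}``
  with the apparent T1* corrected to true T1 via ``T1 = T1*(B/A − 1)``.

All functions are elementwise: they accept scalars or numpy arrays for the
relaxation-time arguments.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple, Union

import numpy as np

ArrayLike = Union[float, np.ndarray]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpinEchoParams:
    """Spin-echo sequence timing (ms)."""

    tr: float
    te: float

    def __post_init__(self) -> None:
        if not self.tr > 0:
            raise ValueError(f"TR must be positive, got {self.tr}")
        if not 0 <= self.te < self.tr:
            raise ValueError(f"need 0 <= TE < TR, got TE={self.te}, TR={self.tr}")


@dataclass(frozen=True)
class MPRAGEParams:
    """MPRAGE sequence parameters.

    tr is the inter-echo repetition time of the readout train (ms), te the
    echo time (carried but unused — T2* decay is ignored), alpha the
    excitation flip angle in degrees, ti the inversion time from the
    inversion pulse to the first readout (ms), trec the recovery period
    after the readout train (ms) and n the number of phase-encoding steps.
    """

    tr: float
    te: float
    alpha: float
    ti: float
    trec: float
    n: int

    def __post_init__(self) -> None:
        if not self.tr > 0:
            raise ValueError(f"TR must be positive, got {self.tr}")
        if not 0 <= self.alpha < 90:
            raise ValueError(f"need 0 <= alpha < 90 deg, got {self.alpha}")
        if not self.ti > 0:
            raise ValueError(f"TI must be positive, got {self.ti}")
        if self.trec < 0:
            raise ValueError(f"Trec must be >= 0, got {self.trec}")
        if self.n < 4 or self.n % 2:
            raise ValueError(f"N must be even and >= 4, got {self.n}")

    @property
    def center_index(self) -> int:
        """Readout index at the center of k-space (linear ordering)."""
        return self.n // 2 - 1


@dataclass(frozen=True)
class LookLockerFit:
    """Parameters of the Look-Locker recovery A − B·e^{−TI/T1*}."""

    a: float
    b: float
    t1star: float
    residual: float = 0.0
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid and not self.t1star > 0:
            raise ValueError(f"T1* must be positive, got {self.t1star}")


@dataclass(frozen=True)
class TissueRef:
    """Literature relaxation parameters of one tissue at 3 T.

    t1/t2 in ms, rho relative to water; sigmas are the literature spreads
    used by the phantom's heterogeneity model (0 = fixed value).
    """

    t1: float
    t2: float
    rho: float
    t1_sigma: float = 0.0
    t2_sigma: float = 0.0
    rho_sigma: float = 0.0

    def __post_init__(self) -> None:
        if min(self.t1, self.t2, self.rho) <= 0:
            raise ValueError("tissue means must be positive")


@dataclass(frozen=True)
class ReferenceParams:
    """Healthy brain tissue MR parameters at 3 T used as internal references.

    Defaults: GM T1=1331±57, T2=110±8.7, ρ=0.807±0.016; WM T1=832±44,
    T2=79.6±2.6, ρ=0.679±0.0168; CSF T1 fixed at 2500 (chosen to keep
    GM/WM contrast; literature values range 2000–4000 ms), T2=1447±52 —
    long enough that echo-time decay is negligible — and ρ=1 by definition.
    """

    gm: TissueRef = TissueRef(1331.0, 110.0, 0.807, 57.0, 8.7, 0.016)
    wm: TissueRef = TissueRef(832.0, 79.6, 0.679, 44.0, 2.6, 0.0168)
    csf: TissueRef = TissueRef(2500.0, 1447.0, 1.0, 0.0, 52.0, 0.0)

    def __post_init__(self) -> None:
        if self.csf.rho != 1:
            raise ValueError("CSF proton density is the water reference (rho=1)")

    def tissues(self) -> Dict[str, TissueRef]:
        return {"gm": self.gm, "wm": self.wm, "csf": self.csf}


# ---------------------------------------------------------------------------
# spin echo
# ---------------------------------------------------------------------------

def _require_positive(**kwargs: ArrayLike) -> None:
    for name, value in kwargs.items():
        if np.any(np.asarray(value) <= 0):
            raise ValueError(f"{name} must be positive")


def se_signal(
    t1: ArrayLike,
    t2: ArrayLike,
    rho: ArrayLike,
    params: SpinEchoParams,
    k: float = 1.0,
) -> ArrayLike:
    """T1-weighted spin-echo signal k·ρ·(1 − e^{−TR/T1})·e^{−TE/T2}."""
    _require_positive(t1=t1, t2=t2, k=k)
    if np.any(np.asarray(rho) < 0):
        raise ValueError("rho must be non-negative")
    t1 = np.asarray(t1, float)
    t2 = np.asarray(t2, float)
    out = k * np.asarray(rho, float) * (1.0 - np.exp(-params.tr / t1)) * np.exp(
        -params.te / t2
    )
    return out if out.ndim else float(out)


def se_t1_signal(t1: ArrayLike, params: SpinEchoParams, k: float = 1.0) -> ArrayLike:
    """Purely T1-weighted spin-echo signal k·(1 − e^{−TR/T1}).

    Equals :func:`se_signal` with the T2 decay and proton density divided
    out using reference values — the quantity the per-slice gain fit and
    the analytic inversion operate on.
    """
    _require_positive(t1=t1, k=k)
    t1 = np.asarray(t1, float)
    out = k * (1.0 - np.exp(-params.tr / t1))
    return out if out.ndim else float(out)


def se_invert(s_t1: float, k: float, tr: float) -> float:
    """Invert k·(1 − e^{−TR/T1}) for T1: scalar form, strict domain.

    Raises for signals outside (0, k); the volume form
    :func:`se_invert_volume` flags such voxels invalid instead.
    """
    _require_positive(k=k, tr=tr)
    if not 0 < s_t1 < k:
        raise ValueError(f"signal {s_t1} outside the invertible range (0, {k})")
    return -tr / math.log(1.0 - s_t1 / k)


def se_invert_volume(
    s_t1: np.ndarray, k: float, tr: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Elementwise spin-echo inversion with an invalid-voxel mask.

    Returns (t1, valid); voxels with signal <= 0 or >= k are invalid and
    carry t1 = 0.
    """
    _require_positive(k=k, tr=tr)
    s = np.asarray(s_t1, float)
    valid = (s > 0) & (s < k)
    ratio = np.where(valid, s / k, 0.5)
    t1 = np.where(valid, -tr / np.log1p(-ratio), 0.0)
    return t1, valid


# ---------------------------------------------------------------------------
# MPRAGE
# ---------------------------------------------------------------------------

def mprage_signal(
    t1: ArrayLike,
    m0: ArrayLike,
    params: MPRAGEParams,
    n: Optional[int] = None,
) -> ArrayLike:
    """Steady-state MPRAGE longitudinal magnetization at readout index n.

    One cycle is: perfect inversion, TI of free recovery, N spoiled
    gradient-echo readouts at (α, TR), then Trec of free recovery.  The
    closed form solves the single-cycle affine map for its fixed point and
    reads out the magnetization just before the (n+1)-th α pulse; the
    default n = N/2 − 1 is the center of k-space, which sets image
    contrast.  Linear in m0.
    """
    _require_positive(t1=t1, m0=m0)
    if n is None:
        n = params.center_index
    if not 0 <= n < params.n:
        raise ValueError(f"readout index {n} outside [0, {params.n})")
    t1 = np.asarray(t1, float)
    delta = np.exp(-params.tr / t1)
    c = math.cos(math.radians(params.alpha))
    q = c * delta
    e_ti = np.exp(-params.ti / t1)
    e_rec = np.exp(-params.trec / t1)

    q_train = q ** params.n
    # magnetization gained over the full train, in units of M0
    gain_train = (1.0 - delta) * (1.0 - q_train) / (1.0 - q)
    # fixed point of the cycle map: magnetization just before inversion
    m_pre_inv = ((1.0 - e_rec) + e_rec * (gain_train + q_train * (1.0 - e_ti))) / (
        1.0 + e_rec * q_train * e_ti
    )
    # after inversion and TI of recovery
    m_start = (1.0 - e_ti) - m_pre_inv * e_ti
    q_n = q ** n
    m_n = (1.0 - delta) * (1.0 - q_n) / (1.0 - q) + m_start * q_n
    out = np.asarray(m0, float) * m_n
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Look-Locker
# ---------------------------------------------------------------------------

def looklocker_signal(ti: ArrayLike, fit: LookLockerFit) -> ArrayLike:
    """Look-Locker recovery A − B·e^{−TI/T1*}."""
    if np.any(np.asarray(ti) < 0):
        raise ValueError("TI must be >= 0")
    ti = np.asarray(ti, float)
    out = fit.a - fit.b * np.exp(-ti / fit.t1star)
    return out if out.ndim else float(out)


def looklocker_correct(fit: LookLockerFit) -> float:
    """Correct the apparent T1* to true T1 = T1*·(B/A − 1).

    The correction compensates the continual perturbation of recovery by
    the readout pulses.  B/A <= 1 is non-physical; the scalar form raises,
    map-level code flags such voxels invalid.
    """
    if fit.a == 0:
        raise ValueError("A must be non-zero")
    ratio = fit.b / fit.a
    if ratio <= 1:
        raise ValueError(f"B/A = {ratio:.4f} <= 1: non-physical Look-Locker fit")
    return fit.t1star * (ratio - 1.0)


# ---------------------------------------------------------------------------
# two-species mixing
# ---------------------------------------------------------------------------

def mix_t1(
    t1a: ArrayLike, t1b: ArrayLike, alpha_frac: ArrayLike, beta_frac: ArrayLike
) -> ArrayLike:
    """Effective T1 of a voxel containing two species in fast exchange.

    With volume fractions α (species a) and β (species b), α + β = 1, the
    voxel relaxes with T1 = T1a·T1b / (β·T1a + α·T1b) — the rate-weighted
    (harmonic-style) mean, e.g. myelinated vs demyelinated tissue.
    """
    _require_positive(t1a=t1a, t1b=t1b)
    a = np.asarray(alpha_frac, float)
    b = np.asarray(beta_frac, float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("volume fractions must be >= 0")
    if not np.allclose(a + b, 1.0):
        raise ValueError("volume fractions must sum to 1")
    denom = b * np.asarray(t1a, float) + a * np.asarray(t1b, float)
    if np.any(denom == 0):
        raise ValueError("zero denominator in two-species mixing")
    out = np.asarray(t1a, float) * np.asarray(t1b, float) / denom
    return out if out.ndim else float(out)
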