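"""Independent oracles used to check closed-form implementations.

These are deliberately naive, loop-based implementations that share no code
with the package internals.
"""
from __future__ import annotations

import math

import numpy as np


def bloch_mprage_signal(t1, m0, params, n=None, cycles=400):
    """Step-by-step Bloch recursion for the MPRAGE steady-state signal.

    Simulates perfect inversion, TI of free recovery, N spoiled
    gradient-echo readouts (cos α scaling + TR recovery), Trec recovery,
    repeated for many cycles; returns the longitudinal magnetization just
    before the (n+1)-th pulse of the final cycle.
    """
    if n is None:
        n = params.n // 2 - 1
    c = math.cos(math.radians(params.alpha))
    mz = m0
    signal = None
    for _ in range(cycles):
        mz = -mz
        mz = m0 + (mz - m0) * math.exp(-params.ti / t1)
        for i in range(params.n):
            if i == n:
                signal = mz
            mz = mz * c
            mz = m0 + (mz - m0) * math.exp(-params.tr / t1)
        mz = m0 + (mz - m0) * math.exp(-params.trec / t1)
    return signal


def effective_range_bruteforce(slope, intercept, pct=0.10, upper=3000.0,
                               step=1.0):
    """Scan the ±pct band condition on a dense T1 grid."""
    x = np.arange(step, upper + step / 2, step)
    y = slope * x + intercept
    ok = ((1 - pct) * x <= y) & (y <= (1 + pct) * x)
    if not ok.any():
        return None
    return float(x[ok][0]), float(x[ok][-1])


def per_tissue_median(t1_map, phantom, label):
    """Median valid T1 over one phantom tissue class."""
    m = (phantom.labels == label) & t1_map.valid_mask
    return float(np.median(t1_map.values[m]))
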