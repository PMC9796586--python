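"""How much does an uncertain T2 reference cost in the derived T1?

The spin-echo conversion divides the measured signal by a literature
e^{-TE/T2} decay factor before inverting for T1.  First-order error
propagation quantifies the cost of that assumption: even a 50% error in a
voxel's true T2 perturbs the derived T1 only mildly at short echo times.
"""
from t1require import SpinEchoParams, t1_uncertainty_from_t2

params = SpinEchoParams(tr=525.0, te=10.0)

for tissue, t1, t2 in [("gray matter", 1331.0, 110.0),
                       ("white matter", 832.0, 79.6)]:
    frac = t1_uncertainty_from_t2(t1, t2, dt2=0.5 * t2, params=params)
    print(f"{tissue}: 50% T2 error -> {100 * frac:.1f}% relative T1 error")

print()
print("At TE=10 ms / TR=525 ms the T2-correction step is benign: a voxel "
      "whose true T2 misses the literature value by half still maps to a "
      "T1 within ~6-9% — the basis for trusting fixed reference T2s.")
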