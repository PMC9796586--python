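# t1require

Retrospective quantitative T1 mapping of the brain from ordinary
T1-weighted MRI, using internal tissue references.

Quantitative T1 relaxation maps are valuable biomarkers — demyelination,
edema and tumor infiltration all shift T1 — but dedicated T1-mapping
sequences are rarely acquired clinically because of scan time. This package
converts the T1-weighted images that *are* routinely acquired (spin-echo
and MPRAGE) into estimated T1 maps, by anchoring each image's signal
equation to the literature relaxation values of three internal reference
tissues: gray matter (GM), white matter (WM) and cerebrospinal fluid (CSF).
Because the scanner's arbitrary intensity scale is fitted away, the derived
maps are comparable across scanners and vendors — useful both as
relaxometry estimates and as a physics-based harmonization step for pooled
or machine-learning studies.

## Method

**Spin echo.** A T1-weighted spin-echo voxel obeys

    S = k · ρ · (1 − e^(−TR/T1)) · e^(−TE/T2)

with scanner gain *k*, proton density ρ and relaxation times T1, T2.
Multiplying by literature per-tissue factors e^(TE/T2_ref)/ρ_ref leaves the
purely T1-weighted

    S_T1 = k · (1 − e^(−TR/T1)).

Per axial slice (to absorb B0-related intensity drift), *k* is fitted by
least squares to the three reference-tissue means of S_T1 against their
literature T1s (GM 1331 ms, WM 832 ms, CSF 2500 ms at 3 T), after which
every in-mask voxel inverts analytically: T1 = −TR / ln(1 − S_T1/k). Only
slices containing all three reference tissues are convertible.

**MPRAGE.** The steady-state signal of the
inversion → N×(α, TR) readout train → Trec cycle has no analytic inverse.
The equilibrium-magnetization scale M0 (linear in the model) is fitted to
the whole-volume reference means, the forward model is tabulated on a 1 ms
T1 grid, and each voxel is inverted through the monotone lookup table.

**Validation machinery.** The package ships a Look-Locker multi-TI
reference fitter (A − B·e^(−TI/T1\*) per voxel, corrected via
T1 = T1\*(B/A − 1)), agreement statistics (OLS regression, Pearson r,
Lin's concordance correlation coefficient, ±10%-band effective range,
CDF conformity distances), first-order error propagation of the T2
assumption, and a seeded digital brain phantom with forward simulators for
all three sequences, so every pipeline can be tested end to end against
known ground truth.

## Worked example

```python
import numpy as np
from t1require import (SpinEchoParams, make_phantom, simulate_spin_echo,
                       require_se_pipeline)

params = SpinEchoParams(tr=525.0, te=10.0)
phantom = make_phantom((64, 64, 64), seed=1, heterogeneity=1.0)
image = simulate_spin_echo(phantom, params, k=1000.0, noise_sd=0.02, seed=1)
t1_map, fits = require_se_pipeline(image, phantom.masks(), params)
for label, name in [(1, "GM"), (2, "WM"), (3, "CSF")]:
    sel = (phantom.labels == label) & t1_map.valid_mask
    print(name, round(float(np.median(t1_map.values[sel])), 1))
```

prints

```
GM 1328.3
WM 850.6
CSF 2297.4
```

— per-tissue medians of the recovered map, in ms, against ground truth
1331 / 832 / 2500: the GM/WM estimates land within ~2% despite 2% image
noise and literature-level tissue heterogeneity (CSF, lying near the flat
top of the saturation-recovery curve at TR = 525 ms, is intrinsically less
stable). The `examples/` directory contains one narrative script per
capability: `error_propagation.py`, `spin_echo_roundtrip.py`,
`mprage_multiscanner.py`, `look_locker_reference.py`. A thin CLI wraps the
same pipelines: `t1require {simulate,se,mprage,ll,compare} --help`.

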