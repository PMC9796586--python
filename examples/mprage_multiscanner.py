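"""Multi-scanner conformity: six MPRAGE protocols, one subject.

Simulates the same phantom under six scanner presets whose inversion times
range from 450 to 1010 ms — grossly different raw contrast — converts each
image to a T1 map via the lookup-table pipeline, and compares the spread of
the cumulative distribution functions before and after conversion.
"""
import numpy as np

from t1require import (
    MULTISCANNER_PRESETS,
    SCANNER_PRESETS,
    cdf_curves,
    make_phantom,
    require_mprage_pipeline,
    simulate_mprage,
)

phantom = make_phantom((64, 64, 64), seed=2, heterogeneity=1.0)
tissue = phantom.labels > 0

maps, raw = [], []
for i, name in enumerate(MULTISCANNER_PRESETS):
    preset = SCANNER_PRESETS[name]
    image = simulate_mprage(phantom, preset, noise_sd=0.02, seed=10 + i)
    t1_map, report = require_mprage_pipeline(image, phantom.masks(),
                                             preset.params)
    maps.append(t1_map)
    d = image.data[tissue]
    raw.append((d - d.min()) / (d.max() - d.min()) + 1e-9)
    gm = np.median(t1_map.values[(phantom.labels == 1) & t1_map.valid_mask])
    print(f"{name:12s} TI={preset.params.ti:6.1f} ms  M0={report['m0']:8.2f}  "
          f"GM median T1={gm:7.1f} ms")

_, _, d_maps = cdf_curves(maps)
_, _, d_raw = cdf_curves(raw)
print()
print(f"max pairwise CDF distance, min-max-normalized raw images: "
      f"{d_raw.max():.3f}")
print(f"max pairwise CDF distance, derived T1 maps:               "
      f"{d_maps.max():.3f}")
print()
print("Raw MPRAGE intensities are incomparable across protocols even after "
      "linear rescaling; converting to T1 collapses the six distributions "
      "onto one another, which is what makes pooled multi-site analysis "
      "possible.")
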