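# Methods

## Signal models

**Spin echo.** The T1-weighted signal is modelled as
`S = k·ρ·(1 − e^(−TR/T1))·e^(−TE/T2)` with a single scanner gain `k`
(transmit/receive gains, ADC range). Dividing out the T2/ρ factors with
per-tissue literature values yields `S_T1 = k·(1 − e^(−TR/T1))`, strictly
decreasing in T1, with the exact inverse `T1 = −TR/ln(1 − S_T1/k)`.
Signals outside `(0, k)` have no model preimage and are flagged invalid
rather than clamped; recovered values above `clamp_max` (default 5000 ms)
are likewise invalidated.

**MPRAGE.** One cycle is: perfect inversion, free recovery for TI, then N
spoiled gradient-echo readouts at flip angle α spaced TR apart, then free
recovery for Trec. Each stage is an affine map of longitudinal
magnetization, so the steady state is the closed-form fixed point of the
composed cycle; the reported signal is the magnetization just before the
(n+1)-th readout pulse, with n = N/2 − 1 (center of k-space under linear
phase-encode ordering, configurable). Two idealizations follow the method
being implemented: T2\* decay at the echo time is ignored, and the sin α
receive factor — a T1-independent scale — is absorbed into the fitted M0.
The closed form is validated in the test suite against an independently
coded step-by-step Bloch recursion (agreement is at machine precision;
the suite asserts < 0.1%).

**Look-Locker.** The multi-TI inversion-recovery samples follow
`S(TI) = A − B·e^(−TI/T1*)` (the decaying-exponential convention); the
apparent `T1*` is corrected to `T1 = T1*(B/A − 1)`. `B/A ≤ 1` is
non-physical and flags the voxel invalid.

**Two-species mixing.** A voxel containing fractions α, β (α + β = 1) of
species with times T1a, T1b relaxes with
`T1 = T1a·T1b/(β·T1a + α·T1b)` — the rate-weighted harmonic form used to
interpret partial-volume and partial-pathology voxels.

## Reference values

Internal references at 3 T: GM T1 = 1331 ± 57 ms, T2 = 110 ± 8.7 ms,
ρ = 0.807 ± 0.016; WM T1 = 832 ± 44 ms, T2 = 79.6 ± 2.6 ms,
ρ = 0.679 ± 0.0168; CSF T1 fixed at 2500 ms (a contrast-preserving choice
within the 2000–4000 ms literature spread; no σ is attached, so CSF T1
does not vary in the phantom), T2 = 1447 ± 52 ms — long enough that echo
time decay is negligible — and ρ = 1 by definition of the water reference.

## Pipelines

**Brain mask.** Union of GM/WM/CSF hard masks, one binary dilation, hole
filling, one erosion (plus a final hole fill); the result always contains
the input union. Probability maps are collapsed to hard masks by voxelwise
argmax with a 0.5 floor on the winning probability.

**T2/ρ correction.** The per-voxel factor `e^(TE/T2_ref)/ρ_ref` is built
from the tissue assignment, propagated to unassigned in-mask voxels from
the nearest assigned voxel (distance transform; counted and logged), then
smoothed with a 2D Gaussian in-plane (across the sagittal and coronal
directions, σ default 2 voxels, renormalized inside the mask so constants
are preserved). Smoothing regularizes segmentation noise in real data but
blurs the piecewise-constant factor at tissue boundaries, so exact
round-trip checks on noiseless phantoms run with σ = 0.

**Gain fits.** Both scale fits are linear in their free parameter and
solved in closed form: `k = Σ s_i f_i / Σ f_i²` with
`f_i = 1 − e^(−TR/T1_i)` over the three reference pairs (per axial slice,
which requires ≥ `min_voxels` = 50 voxels of each tissue in the slice),
and `M0 = Σ s_t g_t / Σ g_t²` with `g_t` the unit-M0 MPRAGE signal (whole
volume — the MPRAGE fit has no per-slice requirement). Both estimators
are scale-equivariant, which makes the derived maps exactly invariant to
any global intensity gain.

**Lookup table.** Default grid 1–5000 ms at 1 ms steps; strict
monotonicity is asserted at build time. If a protocol's signal is
non-monotone over the full grid (possible near signal nulls at long TI),
the table is restricted to the largest strictly monotone subrange, which
must still cover 400–4000 ms; inversion is piecewise-linear interpolation
of the inverse, with out-of-range signals flagged invalid. The lookup
operates on signed model values; real magnitude-reconstructed MPRAGE data
would need polarity restoration first (a known limitation).

**Look-Locker fitting.** Variable projection: for any trial T1\* the
optimal (A, B) are a 2×2 linear least-squares solution, reducing the fit
to a 1D search over T1\*, run on a 64-point logarithmic grid spanning
5–30000 ms and refined by a vectorized ternary search (80 iterations,
bracket ~10⁻¹⁴ of its initial width). This is algebraically the same
optimum a Levenberg–Marquardt fit of all three parameters would find, but
is robust to initialization and fits whole volumes in vectorized form.
Magnitude data are handled by brute force over the K + 1 candidate
sign-flip indices (earliest samples negated), keeping the
minimum-residual fit.

## Phantom and simulators

The phantom stands in for in vivo subjects: nested shells — CSF outside
0.85 of the in-plane radius, GM ribbon 0.55–0.85, WM core inside 0.55,
central CSF "ventricle" inside 0.14 — under a superellipsoid axial profile
(`(1 − w⁸)^{1/2}`), nearly cylindrical so ≥ 80% of non-empty axial slices
contain ≥ 50 voxels of each tissue, satisfying the spin-echo per-slice
precondition. Per-voxel T1/T2/ρ are drawn from normals at the literature
means with spread `heterogeneity·σ`, truncated at ±3σ to keep parameters
physical; `heterogeneity = 0` gives exact means for round-trip testing,
1 gives literature-level spread. Everything is deterministic under a
fixed seed.

Simulators evaluate the closed-form models voxelwise and add Gaussian
noise (sd = `noise_sd` × mean tissue |signal|) inside tissue only;
additive Gaussian keeps the fits unbiased for estimator tests, with an
optional magnitude mode (Rician-like) for the Look-Locker series. The
MPRAGE simulator uses a spatially uniform M0 — matching the model the
lookup pipeline assumes — and signed signals. The multi-scanner presets
reproduce the six published protocols' TR/TE/TI, slice count, FOV and
1 mm voxels; those protocols do not state flip angle, recovery period or
train length, so all presets use α = 9°, Trec = 400 ms (the single-site
Ingenia protocol values) and N = slice count rounded up to even.

What the phantom does *not* emulate: realistic anatomy, partial-volume
mixing at boundaries beyond voxelization, B0/B1 field inhomogeneity,
Rician noise floors in low-SNR regions, or segmentation error (masks are
exact). Passing round-trip tests therefore demonstrate internal
consistency of the estimation machinery — not in vivo accuracy, which in
real data is additionally limited by how well individual tissue means
match the literature references.

## Comparison metrics

`compare_maps` regresses map B on map A (B the map under evaluation, A the
reference; direction configurable by swapping arguments) over jointly
valid voxels and reports OLS slope/intercept, Pearson r and Lin's
concordance correlation coefficient with population (1/n) moments
(`population=False` gives the sample-moment variant). `smooth_maps` is a
normalized box convolution (default use case 4×4×1) restricted to valid
voxels. `effective_range` solves
`(1−pct)·x ≤ slope·x + intercept ≤ (1+pct)·x` analytically from the two
line-band intersections, intersected with (0, 3000] ms by default.
`cdf_curves` evaluates empirical CDFs of valid voxels on a common
2048-point grid and reports pairwise maximum vertical (Kolmogorov)
distances; with `heterogeneity = 0` the T1 distribution is atomic and the
statistic is knife-edged on float rounding, so conformity analyses use
heterogeneous phantoms. Error propagation of the T2 assumption uses the
first-order sensitivities `δS/S = TR·δT1/(T1²(e^{TR/T1} − 1))` and
`δS/S = TE·δT2/T2²`, equated to give
`δT1/T1 = TE·δT2·T1·(e^{TR/T1} − 1)/(TR·T2²)`; the suite cross-checks
this against a numeric re-inversion of the signal model under a perturbed
T2.

## Problem sizes and numerical choices

Test and example volumes are 64³ (phantom minimum 32³), which gives
~150 k in-mask voxels — ample for stable per-tissue medians while keeping
the full suite fast. Monte-Carlo estimator checks use 1000 repetitions at
1% noise (scale fits) and 500 voxels at 2% noise (Look-Locker). Tie-breaks
cannot arise in the lookup inversion (strict monotonicity is enforced);
degenerate constant-signal voxels fail the B/A > 1 check and are flagged
invalid rather than raising.

## Known limitations

- Accuracy in vivo is bounded by how well a subject's healthy-tissue T1s
  match the literature references; pathology in the reference tissues
  biases the calibration.
- The spin-echo conversion requires all three reference tissues in every
  slice; superior/inferior slices without CSF or WM are not converted.
- Magnitude MPRAGE data with signal nulls inside the brain would need
  polarity restoration before lookup inversion.
- The MPRAGE model assumes perfect inversion, instantaneous excitation
  and uniform flip angle; B1 inhomogeneity is out of scope.
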