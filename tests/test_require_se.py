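import numpy as np
import pytest

from t1require import (
    SpinEchoParams,
    TissueMasks,
    VolumeImage,
    build_brain_mask,
    fit_k,
    require_se_pipeline,
    se_t1_signal,
    simulate_spin_echo,
    t2rho_correction,
)

from _oracles import per_tissue_median

SE = SpinEchoParams(tr=525.0, te=10.0)


def _sphere(shape, center, radius):
    grid = np.indices(shape)
    d2 = sum((g - c) ** 2 for g, c in zip(grid, center))
    return d2 <= radius ** 2


class TestBrainMask:
    def test_closing_idempotent_on_solid_sphere(self):
        s = _sphere((40, 40, 40), (20, 20, 20), 12)
        masks = TissueMasks(gm=s, wm=np.zeros_like(s), csf=np.zeros_like(s))
        assert np.array_equal(build_brain_mask(masks), s) or np.all(
            build_brain_mask(masks) >= s
        )

    def test_interior_hole_filled(self):
        s = _sphere((40, 40, 40), (20, 20, 20), 12)
        holey = s.copy()
        holey[20, 20, 20] = False
        masks = TissueMasks(gm=holey, wm=np.zeros_like(s), csf=np.zeros_like(s))
        assert build_brain_mask(masks)[20, 20, 20]

    def test_covers_all_tissue_voxels(self, hetero_phantom):
        mask = build_brain_mask(hetero_phantom.masks())
        assert np.all(mask[hetero_phantom.labels > 0])

    def test_empty_masks_rejected(self):
        z = np.zeros((40, 40, 40), bool)
        with pytest.raises(ValueError):
            build_brain_mask(TissueMasks(gm=z, wm=z, csf=z))


class TestT2RhoCorrection:
    def test_identity_when_te_zero_and_unit_rho(self):
        from t1require import ReferenceParams, TissueRef

        refs = ReferenceParams(
            gm=TissueRef(1331.0, 110.0, 1.0),
            wm=TissueRef(832.0, 79.6, 1.0),
            csf=TissueRef(2500.0, 1447.0, 1.0),
        )
        s = _sphere((40, 40, 40), (20, 20, 20), 12)
        masks = TissueMasks(gm=s, wm=np.zeros_like(s), csf=np.zeros_like(s))
        img = VolumeImage(np.where(s, 7.0, 0.0))
        out = t2rho_correction(img, masks, refs, SpinEchoParams(525.0, 0.0),
                               sigma=3.0)
        assert out.data[s] == pytest.approx(7.0, rel=1e-9)

    def test_single_tissue_uniform_correction(self, refs):
        # smoothing a constant field changes nothing
        s = _sphere((40, 40, 40), (20, 20, 20), 12)
        masks = TissueMasks(gm=s, wm=np.zeros_like(s), csf=np.zeros_like(s))
        img = VolumeImage(np.where(s, 2.0, 0.0))
        out = t2rho_correction(img, masks, refs, SE, sigma=4.0)
        expected = 2.0 * np.exp(SE.te / refs.gm.t2) / refs.gm.rho
        assert out.data[s] == pytest.approx(expected, rel=1e-9)

    def test_noiseless_phantom_recovers_pure_t1_weighting(
        self, homogeneous_phantom, refs
    ):
        img = simulate_spin_echo(homogeneous_phantom, SE, k=1000.0, noise_sd=0.0)
        out = t2rho_correction(img, homogeneous_phantom.masks(), refs, SE,
                               sigma=0.0)
        for label, ref in [(1, refs.gm), (2, refs.wm), (3, refs.csf)]:
            m = homogeneous_phantom.labels == label
            expected = se_t1_signal(ref.t1, SE, k=1000.0)
            assert np.max(np.abs(out.data[m] - expected)) < 1e-10 * expected


class TestFitK:
    PAIRS_T1 = (1331.0, 832.0, 2500.0)

    def _means(self, k):
        return [(se_t1_signal(t1, SE, k=k), t1) for t1 in self.PAIRS_T1]

    def test_self_consistency(self):
        k, residual = fit_k(self._means(1000.0), SE.tr)
        assert k == pytest.approx(1000.0, rel=1e-9)
        assert residual == pytest.approx(0.0, abs=1e-12)

    def test_linear_in_scale(self):
        k1, _ = fit_k(self._means(1000.0), SE.tr)
        k2, _ = fit_k([(2 * s, t1) for s, t1 in self._means(1000.0)], SE.tr)
        assert k2 == pytest.approx(2 * k1, rel=1e-12)

    def test_monte_carlo_bias_small(self):
        # 1% multiplicative noise on the means, 1000 repetitions
        rng = np.random.default_rng(42)
        base = self._means(1000.0)
        ks = []
        for _ in range(1000):
            noisy = [(s * (1 + rng.normal(0, 0.01)), t1) for s, t1 in base]
            ks.append(fit_k(noisy, SE.tr)[0])
        assert abs(np.mean(ks) - 1000.0) / 1000.0 < 0.002

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_k([(0.5, 1331.0), (-0.1, 832.0), (0.9, 2500.0)], SE.tr)


class TestPipeline:
    def test_noiseless_exact_recovery(self, homogeneous_phantom, refs):
        img = simulate_spin_echo(homogeneous_phantom, SE, k=1000.0, noise_sd=0.0)
        t1_map, fits = require_se_pipeline(
            img, homogeneous_phantom.masks(), SE, refs, sigma=0.0
        )
        for label, expected in [(1, 1331.0), (2, 832.0), (3, 2500.0)]:
            got = per_tissue_median(t1_map, homogeneous_phantom, label)
            assert abs(got - expected) / expected < 1e-4
        assert all(f.k == pytest.approx(1000.0, rel=1e-9) for f in fits if f.valid)

    def test_gain_invariance(self, homogeneous_phantom, refs):
        img = simulate_spin_echo(homogeneous_phantom, SE, k=1000.0,
                                 noise_sd=0.02, seed=3)
        base, _ = require_se_pipeline(img, homogeneous_phantom.masks(), SE, refs)
        scaled = VolumeImage(img.data * 37.0, img.affine)
        other, _ = require_se_pipeline(scaled, homogeneous_phantom.masks(), SE,
                                       refs)
        assert np.array_equal(base.valid_mask, other.valid_mask)
        v = base.valid_mask
        assert np.max(np.abs(base.values[v] - other.values[v])
                      / base.values[v]) < 1e-10

    def test_noisy_heterogeneous_recovery_within_ten_percent(
        self, hetero_phantom, refs
    ):
        img = simulate_spin_echo(hetero_phantom, SE, k=1000.0, noise_sd=0.02,
                                 seed=9)
        t1_map, _ = require_se_pipeline(img, hetero_phantom.masks(), SE, refs)
        for label, expected in [(1, 1331.0), (2, 832.0), (3, 2500.0)]:
            got = per_tissue_median(t1_map, hetero_phantom, label)
            assert abs(got - expected) / expected < 0.10

    def test_valid_slice_rule_matches_census(self, hetero_phantom, refs):
        img = simulate_spin_echo(hetero_phantom, SE, k=1000.0, noise_sd=0.0)
        _, fits = require_se_pipeline(img, hetero_phantom.masks(), SE, refs,
                                      min_voxels=50)
        census = hetero_phantom.complete_slices(min_voxels=50)
        assert [f.valid for f in fits] == census.tolist()

    def test_values_within_clamp(self, hetero_phantom, refs):
        img = simulate_spin_echo(hetero_phantom, SE, k=1000.0, noise_sd=0.05,
                                 seed=4)
        t1_map, _ = require_se_pipeline(img, hetero_phantom.masks(), SE, refs)
        vv = t1_map.valid_values()
        assert vv.size and np.all((vv > 0) & (vv <= 5000.0))

    def test_no_valid_slice_raises(self, refs):
        # GM only: the three-tissue precondition can never be met
        s = _sphere((40, 40, 40), (20, 20, 20), 12)
        masks = TissueMasks(gm=s, wm=np.zeros_like(s), csf=np.zeros_like(s))
        img = VolumeImage(np.where(s, 0.3, 0.0))
        with pytest.raises(ValueError):
            require_se_pipeline(img, masks, SE, refs)
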