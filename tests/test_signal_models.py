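import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from t1require import (
    LookLockerFit,
    MPRAGEParams,
    ReferenceParams,
    SCANNER_PRESETS,
    SpinEchoParams,
    looklocker_correct,
    looklocker_signal,
    mix_t1,
    mprage_signal,
    se_invert,
    se_invert_volume,
    se_signal,
    se_t1_signal,
)

from _oracles import bloch_mprage_signal

SE = SpinEchoParams(tr=525.0, te=10.0)


class TestSpinEcho:
    @pytest.mark.parametrize(
        "t1,t2,rho,expected",
        [
            (1e9, 110.0, 0.807, 0.0),          # no longitudinal recovery
            (1331.0, 110.0, 0.807, 0.2402),    # gray matter at study settings
        ],
    )
    def test_signal_values(self, t1, t2, rho, expected):
        assert se_signal(t1, t2, rho, SE) == pytest.approx(expected, abs=5e-4)

    def test_full_recovery_no_decay(self):
        p = SpinEchoParams(tr=1e7, te=0.0)
        assert se_signal(100.0, 80.0, 1.0, p) == pytest.approx(1.0, rel=1e-9)

    def test_monotone_in_t1_and_k(self):
        t1 = np.linspace(100, 5000, 200)
        s = se_signal(t1, 100.0, 0.8, SE)
        assert np.all(np.diff(s) < 0)
        assert se_signal(1000.0, 100.0, 0.8, SE, k=2.0) > se_signal(
            1000.0, 100.0, 0.8, SE, k=1.0
        )

    def test_t1_signal_examples(self):
        assert se_t1_signal(525.0, SE) == pytest.approx(1 - math.exp(-1))
        assert se_t1_signal(1331.0, SE) == pytest.approx(0.3259, abs=5e-5)

    def test_t1_signal_is_corrected_signal(self):
        # algebraic identity: S·e^{TE/T2}/ρ = S_T1
        s = se_signal(900.0, 95.0, 0.75, SE, k=3.0)
        assert s * math.exp(SE.te / 95.0) / 0.75 == pytest.approx(
            se_t1_signal(900.0, SE, k=3.0), rel=1e-12
        )

    def test_invert_examples(self):
        assert se_invert(1 - math.exp(-1), 1.0, 525.0) == pytest.approx(525.0)
        assert se_invert(0.3259, 1.0, 525.0) == pytest.approx(1331.0, rel=1e-3)

    def test_invert_out_of_range_raises(self):
        with pytest.raises(ValueError):
            se_invert(1.2, 1.0, 525.0)
        with pytest.raises(ValueError):
            se_invert(0.0, 1.0, 525.0)

    def test_invert_volume_flags_invalid(self):
        s = np.array([[[0.5, 1.2, -0.1, 0.99]]])
        t1, valid = se_invert_volume(s, 1.0, 525.0)
        assert valid.tolist() == [[[True, False, False, True]]]
        assert t1[0, 0, 1] == 0.0

    @given(st.floats(min_value=100.0, max_value=5000.0))
    @settings(max_examples=200, deadline=None)
    def test_invert_roundtrip_identity(self, t1):
        s = se_t1_signal(t1, SE, k=2.5)
        assert abs(se_invert(s, 2.5, SE.tr) - t1) / t1 < 1e-10

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            se_signal(-1.0, 100.0, 1.0, SE)
        with pytest.raises(ValueError):
            se_t1_signal(1000.0, SE, k=0.0)
        with pytest.raises(ValueError):
            SpinEchoParams(tr=500.0, te=600.0)


class TestMPRAGE:
    PRESET = SCANNER_PRESETS["ingenia-hc"].params

    def test_linear_in_m0(self):
        t1 = np.array([400.0, 1331.0, 4000.0])
        assert np.allclose(
            mprage_signal(t1, 2000.0, self.PRESET),
            2 * mprage_signal(t1, 1000.0, self.PRESET),
        )

    def test_alpha_zero_is_pure_inversion_recovery(self):
        # cos α = 1: readouts do not perturb the recovery, so the signal is
        # the inversion-recovery steady state at the same time point
        p = MPRAGEParams(tr=8.0, te=2.89, alpha=0.0, ti=358.0, trec=400.0, n=176)
        t1 = 1331.0
        got = mprage_signal(t1, 1000.0, p)
        oracle = bloch_mprage_signal(t1, 1000.0, p)
        assert got == pytest.approx(oracle, rel=1e-10)

    @pytest.mark.parametrize("name", sorted(SCANNER_PRESETS))
    @pytest.mark.parametrize("t1", [400.0, 832.0, 1331.0, 2500.0, 4000.0])
    def test_closed_form_matches_bloch_recursion(self, name, t1):
        p = SCANNER_PRESETS[name].params
        got = mprage_signal(t1, 1000.0, p)
        oracle = bloch_mprage_signal(t1, 1000.0, p)
        assert abs(got - oracle) < 1e-3 * max(abs(oracle), 1e-9)

    @pytest.mark.parametrize("name", sorted(SCANNER_PRESETS))
    def test_monotone_in_t1_over_working_range(self, name):
        # required for lookup-table uniqueness
        t1 = np.arange(400.0, 4000.0 + 0.5, 1.0)
        s = mprage_signal(t1, 1000.0, SCANNER_PRESETS[name].params)
        assert np.all(np.diff(s) < 0)

    def test_index_validation(self):
        with pytest.raises(ValueError):
            mprage_signal(1000.0, 1000.0, self.PRESET, n=self.PRESET.n)
        with pytest.raises(ValueError):
            MPRAGEParams(tr=8.0, te=3.0, alpha=9.0, ti=358.0, trec=400.0, n=7)


class TestLookLocker:
    def test_signal_limits(self):
        fit = LookLockerFit(a=1000.0, b=2000.0, t1star=900.0)
        assert looklocker_signal(0.0, fit) == pytest.approx(-1000.0)
        assert looklocker_signal(1e9, fit) == pytest.approx(1000.0)
        assert looklocker_signal(900.0, fit) == pytest.approx(264.2, abs=0.1)

    @pytest.mark.parametrize(
        "a,b,t1star,expected",
        [(1000.0, 2000.0, 900.0, 900.0), (800.0, 2000.0, 600.0, 900.0)],
    )
    def test_correction(self, a, b, t1star, expected):
        fit = LookLockerFit(a=a, b=b, t1star=t1star)
        assert looklocker_correct(fit) == pytest.approx(expected)

    def test_correction_nonphysical_raises(self):
        with pytest.raises(ValueError):
            looklocker_correct(LookLockerFit(a=1000.0, b=1000.0, t1star=900.0))

    @given(
        st.floats(min_value=200.0, max_value=4000.0),
        st.floats(min_value=1.2, max_value=3.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_correction_inverts_apparent_t1(self, t1, bover_a):
        # simulate with T1* = T1/(B/A − 1); correction must return T1
        fit = LookLockerFit(a=1.0, b=bover_a, t1star=t1 / (bover_a - 1))
        assert looklocker_correct(fit) == pytest.approx(t1, rel=1e-12)


class TestMixing:
    def test_pure_and_equal_species(self):
        assert mix_t1(900.0, 1500.0, 1.0, 0.0) == pytest.approx(900.0)
        assert mix_t1(1200.0, 1200.0, 0.3, 0.7) == pytest.approx(1200.0)

    def test_equal_mixture_value(self):
        # 2·832·1331/(832+1331), evaluated independently
        assert mix_t1(832.0, 1331.0, 0.5, 0.5) == pytest.approx(1023.9, abs=0.05)

    @given(
        st.floats(min_value=200.0, max_value=4000.0),
        st.floats(min_value=200.0, max_value=4000.0),
        st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_mixture_bounded_by_species(self, t1a, t1b, frac):
        mixed = mix_t1(t1a, t1b, frac, 1.0 - frac)
        assert min(t1a, t1b) - 1e-9 <= mixed <= max(t1a, t1b) + 1e-9

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            mix_t1(800.0, 1300.0, 0.7, 0.7)


def test_reference_defaults_are_3t_literature_values(refs):
    assert (refs.gm.t1, refs.gm.t2, refs.gm.rho) == (1331.0, 110.0, 0.807)
    assert (refs.wm.t1, refs.wm.t2, refs.wm.rho) == (832.0, 79.6, 0.679)
    assert (refs.csf.t1, refs.csf.t2, refs.csf.rho) == (2500.0, 1447.0, 1.0)
    assert ReferenceParams() == refs
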