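"""Rapid-equilibrium partition algebra and slow-variable RHS."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import akrkin as ak
from akrkin.mechanism import InvalidParameterError


def make_params(**kw):
    base = dict(K_NAD=0.16e-3, K_NADH=0.61e-3, k_spec1=16920.0, k_spec2=1580.0)
    base.update(kw)
    return ak.MechanismParams(**base)


class TestPartition:
    def test_apoenzyme_only_limit(self):
        part = ak.partition_active_enzyme(make_params(), 0.0, 0.0, 0.0)
        assert part.f_E == 1.0
        assert part.f_ENAD == part.f_ENADH == part.f_ENAD_I == part.f_ENADH_I == 0.0

    def test_holoenzyme_fraction_at_assay_nad(self):
        # nad/K_NAD = 2.3/0.16 = 14.375 -> f_ENAD = 14.375/15.375
        part = ak.partition_active_enzyme(make_params(), 2.3e-3, 0.0, 0.0)
        assert part.f_ENAD == pytest.approx(14.375 / 15.375, rel=1e-14)
        assert part.f_E == pytest.approx(1.0 / 15.375, rel=1e-14)

    def test_fraction_sum_randomized(self):
        rng = np.random.default_rng(42)
        for _ in range(10_000):
            p = make_params(
                K_NAD=10 ** rng.uniform(-5, -2),
                K_NADH=10 ** rng.uniform(-5, -2),
                K2=10 ** rng.uniform(-8, -3),
                K3=10 ** rng.uniform(-9, -4),
            )
            part = ak.partition_active_enzyme(
                p, 10 ** rng.uniform(-6, -2), 10 ** rng.uniform(-7, -3),
                10 ** rng.uniform(-7, -3))
            assert abs(part.as_array().sum() - 1.0) < 1e-12

    @settings(max_examples=200, derandomize=True)
    @given(
        k2=st.floats(1e-8, 1e-3), k3=st.floats(1e-9, 1e-4),
        nadh=st.floats(0, 1e-3), i_lo=st.floats(0, 1e-4),
        i_step=st.floats(1e-9, 1e-3),
    )
    def test_productive_fraction_monotone_in_inhibitor(self, k2, k3, nadh, i_lo, i_step):
        p = make_params(K2=k2, K3=k3)
        lo = ak.partition_active_enzyme(p, 2.3e-3, nadh, i_lo)
        hi = ak.partition_active_enzyme(p, 2.3e-3, nadh, i_lo + i_step)
        assert hi.f_ENAD <= lo.f_ENAD + 1e-15

    def test_not_determined_constants_reproduce_inhibitor_free(self):
        p = make_params(K2=None, K3=None)
        for i in (0.0, 1e-6, 2e-4):
            part = ak.partition_active_enzyme(p, 2.3e-3, 5e-5, i)
            ref = ak.partition_active_enzyme(p, 2.3e-3, 5e-5, 0.0)
            assert part == ref

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            ak.partition_active_enzyme(make_params(), -1e-6, 0.0, 0.0)

    def test_zero_dissociation_constant_is_invalid_not_absent(self):
        with pytest.raises(InvalidParameterError):
            make_params(K2=0.0)


class TestParamValidation:
    def test_reversible_only_forbids_irreversible_rates(self):
        with pytest.raises(InvalidParameterError):
            make_params(K2=1e-6, k_plus2=5.0, variant="reversible_only")
        make_params(K2=1e-6, variant="reversible_only")  # valid

    def test_parabolic_requires_composite_and_forbids_pair(self):
        with pytest.raises(InvalidParameterError):
            make_params(variant="parabolic")
        with pytest.raises(InvalidParameterError):
            make_params(variant="parabolic", composite3=1e6, K3=1e-8)
        make_params(variant="parabolic", composite3=1e6)  # valid

    def test_composites_only_under_parabolic(self):
        with pytest.raises(InvalidParameterError):
            make_params(composite3=1e6, variant="full")


class TestSlowRHS:
    COND = dict(E_total=0.11e-6, NAD0=2.3e-3, S_total=90e-6, I_conc=10e-6)

    def test_term_by_term_hand_computation(self):
        p = make_params(K2=2e-6, k_plus2=25.0, K3=50e-9, k_plus3=5.0)
        cond = ak.AssayConditions(**self.COND)
        state = ak.SlowState(A=30e-6, B=40e-6, E_inact=0.02e-6)
        # independent evaluation of the stated expressions
        nadh = 45e-6 + 45e-6 - 30e-6 - 40e-6
        nad = 2.3e-3 - nadh
        rN = nad / 0.16e-3
        rH = nadh / 0.61e-3
        D = 1.0 + rN * (1.0 + 10e-6 / 2e-6) + rH * (1.0 + 10e-6 / 50e-9)
        e_act = 0.11e-6 - 0.02e-6
        enad = rN / D * e_act
        exp_dA = -16920.0 * enad * 30e-6
        exp_dB = -1580.0 * enad * 40e-6
        exp_dE = (25.0 * 10e-6 * (rN * 5.0 / D)
                  + 5.0 * 10e-6 * (rH * 200.0 / D)) * e_act
        got = ak.slow_rhs(state, p, cond)
        assert got.dA == pytest.approx(exp_dA, rel=1e-12)
        assert got.dB == pytest.approx(exp_dB, rel=1e-12)
        assert got.dE_inact == pytest.approx(exp_dE, rel=1e-12)

    def test_parabolic_inactivation_term(self):
        p = make_params(composite3=2e6, variant="parabolic")
        cond = ak.AssayConditions(**self.COND)
        state = ak.SlowState(A=30e-6, B=40e-6, E_inact=0.0)
        nadh = 20e-6
        rN = (2.3e-3 - nadh) / 0.16e-3
        rH = nadh / 0.61e-3
        D = 1.0 + rN + rH  # no reversible inhibitor terms in this variant
        exp_dE = 2e6 * (10e-6) ** 2 * rH / D * 0.11e-6
        got = ak.slow_rhs(state, p, cond)
        assert got.dE_inact == pytest.approx(exp_dE, rel=1e-12)

    def test_no_enzyme_no_flux(self):
        p = make_params(K2=2e-6, k_plus2=25.0)
        cond = ak.AssayConditions(**{**self.COND, "E_total": 0.0})
        got = ak.slow_rhs(ak.SlowState(A=30e-6, B=40e-6), p, cond)
        assert got.dA == got.dB == got.dE_inact == 0.0

    def test_no_inhibitor_pathway_no_inactivation(self):
        p = make_params(K2=2e-6, K3=50e-9)  # k_plus = 0
        cond = ak.AssayConditions(**{**self.COND, "I_conc": 0.0})
        got = ak.slow_rhs(ak.SlowState(A=30e-6, B=40e-6), p, cond)
        assert got.dE_inact == 0.0
        assert got.dA < 0

    def test_invalid_state_rejected(self):
        p = make_params()
        cond = ak.AssayConditions(**self.COND)
        with pytest.raises(ValueError):
            ak.slow_rhs(ak.SlowState(A=50e-6, B=50e-6), p, cond)  # A > A0
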