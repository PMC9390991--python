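"""Model core: drive waveform, HY5 quasi-steady state, RHS arithmetic,
closed-form steady states and structural monotonicities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermogrowth.environment import EnvironmentRegime
from thermogrowth.genotypes import Genotype, WT
from thermogrowth.model import (ParameterSet, State, cop1_target, elf3_drive,
                                free_running_mean_drive, hy5_qss, rhs,
                                rhs_constant_forcing, steady_state_constant)


class TestElf3Drive:
    def test_peak_normalized_to_one_at_22C(self, simple_params):
        regime = EnvironmentRegime(8.0, 22.0)
        # dusk window starts at lights-off (t=8) and lasts w_E hours
        assert elf3_drive(9.0, regime, simple_params) == pytest.approx(1.0)

    def test_trough_is_basal_fraction(self, simple_params):
        regime = EnvironmentRegime(8.0, 22.0)
        assert elf3_drive(4.0, regime, simple_params) == pytest.approx(
            simple_params.b_E)

    def test_warmth_damps_drive(self, simple_params):
        p = simple_params.replace(rho_E=0.05)
        regime = EnvironmentRegime(8.0, 28.0)
        assert elf3_drive(9.0, regime, p) == pytest.approx(math.exp(-0.3))

    def test_free_running_mean_in_constant_conditions(self, simple_params):
        p = simple_params
        mean = p.b_E + (1 - p.b_E) * p.w_E / 24.0
        for D in (0.0, 24.0):
            regime = EnvironmentRegime(D, 22.0)
            assert elf3_drive(13.0, regime, p) == pytest.approx(mean)

    def test_window_wraps_past_midnight(self, simple_params):
        p = simple_params.replace(w_E=6.0)
        regime = EnvironmentRegime(20.0, 22.0)  # dusk 20 h, window into next dawn
        assert elf3_drive(25.0, regime, p) == pytest.approx(1.0)  # tau=1 < 2
        assert elf3_drive(27.0, regime, p) == pytest.approx(p.b_E)


class TestHy5:
    def test_limits(self, simple_params):
        p = simple_params
        assert hy5_qss(0.0, p, 1.0) == pytest.approx(p.Y0)
        assert hy5_qss(5.0, p, 0.0) == 0.0
        assert hy5_qss(p.K_C, p, 1.0) == pytest.approx(p.Y0 / 2)

    def test_decreasing_in_cop1(self, simple_params):
        ys = [hy5_qss(c, simple_params) for c in (0.0, 0.5, 1.0, 4.0)]
        assert all(a > b for a, b in zip(ys, ys[1:]))

    def test_degenerate_kc_rejected(self, simple_params):
        with pytest.raises(ValueError, match="K_C"):
            hy5_qss(1.0, simple_params.replace(K_C=0.0))


class TestRhs:
    def test_dark_reversion_arithmetic(self, simple_params):
        # L=0, B=0.5, k_dB=0.1, q(22)=1 -> dB/dt = -0.05
        s = np.array([0.5, 0.0, 0.0, 0.0, 1.0])
        d = rhs_constant_forcing(s, L=0, T=22.0, drive=0.0,
                                 p=simple_params, g=WT)
        assert d[0] == pytest.approx(-0.05)

    def test_phyb_null_is_absorbing(self, simple_params):
        g = Genotype("phyB-9", g_B=0.0)
        regime = EnvironmentRegime(8.0, 22.0)
        for t in (-22.0, 2.0, 10.0):
            s = np.array([0.0, 0.1, 0.2, 0.3, 1.0])
            assert rhs(t, s, simple_params, g, regime)[0] == 0.0

    def test_dark_reversion_q10_ratio_is_exact(self, simple_params):
        s = np.array([0.7, 0.0, 0.0, 0.0, 1.0])
        d22 = rhs_constant_forcing(s, 0, 22.0, 0.0, simple_params, WT)[0]
        d28 = rhs_constant_forcing(s, 0, 28.0, 0.0, simple_params, WT)[0]
        assert d28 / d22 == pytest.approx(simple_params.Q10_B ** 0.6, rel=1e-12)
        assert d28 < d22 < 0  # strictly faster reversion when warm

    def test_nonfinite_state_rejected(self, simple_params):
        regime = EnvironmentRegime(8.0, 22.0)
        with pytest.raises(FloatingPointError, match="non-finite"):
            rhs(1.0, np.array([np.nan, 0, 0, 0, 0.5]), simple_params, WT, regime)

    def test_growth_rate_bounded(self, simple_params):
        p = simple_params
        rng = np.random.default_rng(0)
        for _ in range(200):
            s = rng.uniform(0, 10, size=5)
            dH = rhs_constant_forcing(s, 1, 28.0, 1.0, p, WT)[4]
            assert p.v0 <= dH <= p.v0 + p.v_max

    def test_cop1_target_temperature_structure(self, simple_params):
        p = simple_params
        # night target is temperature-blind; day target non-decreasing in T,
        # capped at the night ceiling
        assert cop1_target(0, 22.0, p) == cop1_target(0, 35.0, p) == p.C_dark
        days = [cop1_target(1, T, p) for T in (22.0, 25.0, 28.0, 60.0)]
        assert all(a <= b for a, b in zip(days, days[1:]))
        assert days[-1] <= p.C_dark


class TestSteadyState:
    def test_dark_has_no_active_phyb(self, simple_params):
        s = steady_state_constant(simple_params, WT, L=0, T=22.0, drive=0.3)
        assert s.B == 0.0

    def test_light_balance_closed_form(self, simple_params):
        p = simple_params.replace(k_pB=1.0, k_rB=0.0, k_dB=1.0, Q10_B=2.0)
        s = steady_state_constant(p, WT, L=1, T=22.0, drive=0.3)
        assert s.B == pytest.approx(0.5)

    def test_cop1_null_releases_hy5(self, simple_params):
        g = Genotype("cop1", g_C=0.0)
        s = steady_state_constant(simple_params, g, L=0, T=22.0, drive=0.3)
        assert s.C == 0.0
        assert hy5_qss(s.C, simple_params, g.g_Y) == pytest.approx(
            simple_params.Y0)

    @pytest.mark.parametrize("L,T,D", [(0, 22.0, 0.0), (1, 28.0, 24.0)])
    def test_residual_below_1e10(self, simple_params, L, T, D):
        """The closed forms zero the RHS to 1e-10 in every component."""
        p = simple_params
        regime = EnvironmentRegime(D, T)
        drive = elf3_drive(30.0, regime, p)  # free-running constant drive
        s = steady_state_constant(p, WT, L=L, T=T, drive=drive)
        deriv = rhs(30.0, s.to_array(), p, WT, regime)
        assert np.all(np.abs(deriv[:4]) < 1e-10)

    def test_zero_decay_rejected(self, simple_params):
        with pytest.raises(ValueError, match="decay"):
            steady_state_constant(simple_params.replace(k_dB=0.0), WT,
                                  L=0, T=22.0, drive=0.3)


nonneg_state = st.lists(st.floats(0.0, 10.0), min_size=5, max_size=5)


@given(state=nonneg_state, zero_idx=st.integers(0, 3),
       L=st.sampled_from([0, 1]), T=st.sampled_from([22.0, 28.0]))
@settings(deadline=None, max_examples=100)
def test_forward_invariance_on_boundary(state, zero_idx, L, T):
    """With any component at zero, its derivative is non-negative: the flow
    never leaves the non-negative orthant."""
    p = ParameterSet(
        k_pB=1.0, k_rB=0.5, k_dB=0.1, Q10_B=2.0,
        a_E=0.4, d_E=0.3, b_E=0.2, w_E=4.0, rho_E=0.05,
        C_dark=1.0, C_light=0.2, eps_C=0.2, tau_C=1.0,
        a_P=1.0, K_E=0.5, h_E=2.0, d_P=0.5, beta_B=4.0, beta_C=3.0,
        Y0=1.0, K_C=0.5,
        v0=0.01, v_max=0.1, K_G=1.0, n_G=2.0, K_Bg=0.5, K_Eg=1.0, K_Yg=1.0,
        H0=0.5)
    s = np.array(state)
    s[zero_idx] = 0.0
    d = rhs_constant_forcing(s, L, T, 0.7, p, WT)
    assert d[zero_idx] >= 0.0


def test_parameterset_json_roundtrip_lossless(simple_params):
    p2 = ParameterSet.from_json(simple_params.to_json())
    assert p2.to_dict() == simple_params.to_dict()


def test_parameterset_invariants_enforced():
    base = dict(k_pB=1, k_rB=1, k_dB=0.1, Q10_B=2, a_E=1, d_E=0.3, b_E=0.2,
                w_E=4, rho_E=0.05)
    with pytest.raises(ValueError, match="Q10_B"):
        ParameterSet(**{**base, "Q10_B": 0.5})
    with pytest.raises(ValueError, match="b_E"):
        ParameterSet(**{**base, "b_E": 1.5})
    with pytest.raises(ValueError, match="C_light"):
        ParameterSet(**base, C_dark=0.5, C_light=1.0)
    with pytest.raises(ValueError, match="finite"):
        ParameterSet(**{**base, "k_pB": -1.0})


def test_monotone_interaction_structure(simple_params):
    """PIF production falls with ELF3; PIF removal rises with phyB and falls
    with COP1; growth input A rises with PIF/COP1 and falls with phyB/ELF3."""
    p = simple_params

    def dP(E=0.0, B=0.0, C=0.0, P=1.0):
        return rhs_constant_forcing(np.array([B, E, C, P, 1.0]),
                                    0, 22.0, 0.0, p, WT)[3]

    assert dP(E=0.0) > dP(E=1.0) > dP(E=3.0)
    assert dP(B=0.0) > dP(B=1.0)          # more phyB -> faster removal
    assert dP(C=2.0) > dP(C=0.0)          # more COP1 -> stabilized

    def dH(P=1.0, B=0.0, E=0.0, C=0.0):
        return rhs_constant_forcing(np.array([B, E, C, P, 1.0]),
                                    0, 22.0, 0.0, p, WT)[4]

    assert dH(P=2.0) > dH(P=1.0)
    assert dH(B=1.0) < dH(B=0.0)
    assert dH(E=1.0) < dH(E=0.0)
    assert dH(C=1.0) > dH(C=0.0)          # COP1 clears HY5 from promoters
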