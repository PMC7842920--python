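"""Unit and property tests for the model's algebraic building blocks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calbeta import (
    CellState,
    DoseParams,
    InjectionProtocol,
    abeta_drive,
    er_calcium,
    gprotein_drive,
    ipr_open_probability,
    plc_max_rate,
    rhs_full,
    rhs_reduced_cy,
    rhs_subsystem_cyp,
    serca_flux,
    steady_state,
)


class TestInjectionDrive:
    def test_zero_before_injection(self):
        proto = InjectionProtocol(a=10.0, t1=2.0, r=0.001)
        assert abeta_drive(0.0, proto) == 0.0
        assert abeta_drive(1.999, proto) == 0.0

    def test_full_dose_at_injection_time(self):
        proto = InjectionProtocol(a=10.0, t1=2.0, r=0.001)
        assert abeta_drive(2.0, proto) == pytest.approx(10.0)

    def test_exponential_decay(self):
        proto = InjectionProtocol(a=10.0, t1=2.0, r=0.001)
        assert abeta_drive(1002.0, proto) == pytest.approx(10.0 * np.exp(-1.0))

    def test_frozen_mode_is_constant(self):
        proto = InjectionProtocol(a=3.0, frozen=True)
        t = np.array([0.0, 1.0, 2.0, 1e6])
        assert np.all(abeta_drive(t, proto) == 3.0)

    def test_vectorized_matches_scalar(self):
        proto = InjectionProtocol(a=5.0, t1=2.0, r=0.01)
        t = np.linspace(0.0, 100.0, 33)
        vec = abeta_drive(t, proto)
        assert vec == pytest.approx([abeta_drive(ti, proto) for ti in t])

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            InjectionProtocol(a=-1.0)


class TestTransductionTerms:
    def test_gprotein_drive_half_activation(self, small):
        assert gprotein_drive(0.0, small) == 0.0
        assert gprotein_drive(small.K_R, small) == pytest.approx(small.V_R / 2)

    def test_gprotein_drive_at_unit_dose(self, small):
        # V_R q/(K_R + q) = 7.4/4468 for the small-dose constants at q = 1
        assert gprotein_drive(1.0, small) == pytest.approx(7.4 / 4468.0)

    def test_plc_max_rate_hill_landmarks(self, small):
        assert plc_max_rate(0.0, small) == pytest.approx(small.V_0)
        assert plc_max_rate(small.K_Q, small) == pytest.approx(
            small.V_0 + small.V_Q / 2)
        assert plc_max_rate(1e9, small) == pytest.approx(
            small.V_0 + small.V_Q, rel=1e-6)

    def test_serca_hill_landmarks(self, small):
        assert serca_flux(0.0, small) == 0.0
        assert serca_flux(small.K_s, small) == pytest.approx(small.V_s / 2)
        assert serca_flux(1e6, small) == pytest.approx(small.V_s, rel=1e-6)

    def test_er_calcium_conservation(self, small):
        c = np.array([0.0, 0.05, small.c_t])
        ce = er_calcium(c, small)
        assert np.allclose(c + ce / small.gamma, small.c_t)
        assert er_calcium(0.05, DoseParams.small_doses()) == pytest.approx(
            7 * (2 - 0.05))

    def test_er_calcium_rejects_overfull_cytosol(self, small):
        with pytest.raises(ValueError):
            er_calcium(small.c_t + 0.1, small)


class TestOpenProbability:
    def test_boundary_cases(self, small):
        assert ipr_open_probability(0.5, 1.0, 0.3, small) == 0.0
        assert ipr_open_probability(0.5, 0.2, 0.0, small) == 0.0
        assert ipr_open_probability(1e9, 0.0, 1e9, small) == pytest.approx(
            1.0, rel=1e-6)

    @settings(deadline=None, max_examples=60)
    @given(c=st.floats(0.0, 10.0), y=st.floats(0.0, 1.0), p=st.floats(0.0, 10.0))
    def test_stays_in_unit_interval(self, c, y, p):
        po = ipr_open_probability(c, y, p, DoseParams.small_doses())
        assert 0.0 <= po <= 1.0

    @settings(deadline=None, max_examples=40)
    @given(c=st.floats(0.01, 5.0), y=st.floats(0.0, 0.99), p=st.floats(0.01, 5.0))
    def test_monotone_in_p_and_y(self, c, y, p):
        params = DoseParams.small_doses()
        assert ipr_open_probability(c, y, p * 1.1, params) >= \
            ipr_open_probability(c, y, p, params)
        assert ipr_open_probability(c, y + 0.01, p, params) <= \
            ipr_open_probability(c, y, p, params)


class TestParameterSets:
    def test_regimes_are_distinct_and_loadable(self, small, large):
        assert small != large
        assert small.K_R == 4467.0 and large.K_R == 2000.0
        assert DoseParams.from_dict(small.to_dict()) == small

    def test_derived_ip3_constants(self, small):
        d = small.derived_ip3
        assert d.tau_p == pytest.approx(1.0 / (small.k_3k + small.k_5p))
        assert d.eta == pytest.approx(small.k_3k / (small.k_3k + small.k_5p))
        assert 0.0 < d.eta < 1.0

    def test_invalid_parameters_rejected(self, small):
        with pytest.raises(ValueError):
            small.with_updates(K1=-0.1)
        with pytest.raises(KeyError):
            DoseParams.from_dict({"bogus": 1.0})

    def test_cellstate_invariants(self, small):
        with pytest.raises(ValueError):
            CellState(c=2.5, y=0.5, p=0.1, PLC=0.1, G=0.1).validate(small)
        with pytest.raises(ValueError):
            CellState(c=0.05, y=1.5, p=0.1, PLC=0.1, G=0.1).validate(small)


class TestRightHandSides:
    def test_zero_at_steady_state(self, small):
        ss = steady_state(small, 0.0)
        d = rhs_full(0.0, ss, small, InjectionProtocol(a=0.0, frozen=True))
        assert np.linalg.norm(d) < 1e-9

    def test_y_boundary_keeps_y_nonnegative(self, small):
        proto = InjectionProtocol(a=1.0, frozen=True)
        d = rhs_full(0.0, np.array([0.05, 0.0, 0.1, 0.01, 0.01]), small, proto)
        assert d[1] >= 0.0  # inactivation gain * (1 - y) with y = 0

    def test_subsystem_consistency_with_full_model(self, small):
        proto = InjectionProtocol(a=1.0, frozen=True)
        x = np.array([0.08, 0.3, 0.2, 0.007, 0.002])
        full = rhs_full(0.0, x, small, proto)
        sub = rhs_subsystem_cyp(0.0, x[:3], x[3], small, proto)
        assert sub == pytest.approx(full[:3])

    def test_zero_dose_is_autonomous(self, small):
        x = np.array([0.05, 0.4, 0.15, 0.005, 0.002])
        protos = [InjectionProtocol(a=0.0, t1=t1, r=r)
                  for t1, r in [(2.0, 0.001), (50.0, 0.1)]]
        derivs = [rhs_full(t, x, small, pr) for pr in protos for t in (0.0, 77.0)]
        for d in derivs[1:]:
            assert d == pytest.approx(derivs[0])

    def test_reduced_model_at_zero_ip3(self, small):
        c, y = 0.05, 0.3
        d = rhs_reduced_cy(0.0, (c, y), 0.0, small)
        expected_dc = small.J_ER * (small.gamma * (small.c_t - c) - c) \
            - serca_flux(c, small)
        assert d[0] == pytest.approx(expected_dc)

    def test_nonfinite_state_rejected(self, small):
        with pytest.raises(ValueError):
            rhs_full(0.0, np.array([np.nan, 0.5, 0.1, 0.01, 0.01]), small,
                     InjectionProtocol())
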