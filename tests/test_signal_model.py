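"""Closed-form steady-state models vs the discrete Bloch recursion oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refblochi import (
    SequenceParams,
    TissueState,
    bloch_recursion_oracle,
    f_imperfect,
    f_prime,
    f_weight,
    mzss_ir,
    mzss_noinv,
    mzss_simple,
    perturbation_coefficient,
)
from refblochi.signal_model import ParameterError, g_noinv


@st.composite
def valid_protocols(draw):
    tr = draw(st.floats(2.0, 8.0))
    n = draw(st.integers(1, 60))
    ti = draw(st.floats(80.0, 400.0))
    slack = draw(st.floats(10.0, 600.0))
    flip = draw(st.floats(2.0, 80.0))
    beta = draw(st.floats(0.7, 1.0))
    return SequenceParams(tr_ms=tr, flip_deg=flip, ti_ms=ti,
                          rr_ms=ti + n * tr + slack, n_views=n,
                          inversion_factor=beta)


class TestPerturbationCoefficient:
    def test_unity_for_single_90_degree_pulse(self):
        params = SequenceParams(tr_ms=5.0, flip_deg=89.9999999, ti_ms=300.0,
                                rr_ms=900.0, n_views=1)
        assert perturbation_coefficient(params, 280.0) == pytest.approx(1.0, abs=1e-6)

    def test_unity_in_zero_angle_limit(self):
        params = SequenceParams(tr_ms=5.0, flip_deg=1e-7, ti_ms=300.0,
                                rr_ms=900.0, n_views=33)
        assert perturbation_coefficient(params, 280.0) == pytest.approx(1.0, abs=1e-9)

    def test_known_value_matches_recursion_derivation(self):
        # frozen from the Bloch recursion oracle: solve the steady-state
        # expression for p at TR=5, alpha=15 deg, N=33, T1=280
        params = SequenceParams(tr_ms=5.0, flip_deg=15.0, ti_ms=300.0,
                                rr_ms=950.0, n_views=33)
        assert perturbation_coefficient(params, 280.0) == pytest.approx(
            1.28935, abs=2e-4)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(valid_protocols(), st.floats(80.0, 1500.0))
    def test_at_least_one_everywhere(self, params, t1):
        assert perturbation_coefficient(params, t1) >= 1.0 - 1e-9

    def test_rejects_nonpositive_t1(self):
        params = SequenceParams(5.0, 15.0, 300.0, 900.0, 33)
        with pytest.raises(ParameterError):
            perturbation_coefficient(params, -10.0)


class TestSimpleModel:
    def test_long_t1_limit_vanishes(self):
        assert mzss_simple(1e9, 1.0, 300.0, 900.0) == pytest.approx(0.0, abs=1e-6)

    def test_full_recovery_limit(self):
        # TI huge with an even larger RR: magnetization fully recovered
        assert mzss_simple(280.0, 2.5, 1e5, 2e5) == pytest.approx(2.5, rel=1e-10)

    def test_known_value(self):
        # 1 - 2 exp(-300/280) + exp(-900/280), evaluated independently
        assert mzss_simple(280.0, 1.0, 300.0, 900.0) == pytest.approx(
            0.3551463162, abs=1e-9)


class TestOracleEquivalence:
    """The re-derived closed forms must reproduce the period-by-period recursion."""

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(valid_protocols(), st.floats(80.0, 1500.0))
    def test_inversion_model_matches_oracle(self, params, t1):
        state = TissueState(t1_ms=t1, m0=1.0)
        closed = (mzss_ir(params, state) if params.inversion_factor == 1.0
                  else f_imperfect(params, t1))
        assert abs(closed - bloch_recursion_oracle(params, state)) < 1e-9

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(valid_protocols(), st.floats(80.0, 1500.0))
    def test_no_inversion_model_matches_oracle(self, params, t1):
        state = TissueState(t1_ms=t1, m0=1.0)
        oracle = bloch_recursion_oracle(params, state, invert=False)
        assert abs(mzss_noinv(params, state) - oracle) < 1e-9

    def test_reduces_to_simple_model_at_90_degrees_single_view(self):
        params = SequenceParams(tr_ms=5.0, flip_deg=89.99999999, ti_ms=300.0,
                                rr_ms=900.0, n_views=1)
        ir = mzss_ir(params, TissueState(300.0, 1.0))
        assert ir == pytest.approx(mzss_simple(300.0, 1.0, 300.0, 900.0), abs=1e-8)

    def test_frozen_oracle_value(self):
        params = SequenceParams(5.0, 15.0, 300.0, 950.0, 33)
        assert mzss_ir(params, TissueState(280.0, 1.0)) == pytest.approx(
            0.354505, abs=1e-5)

    def test_linear_in_m0(self):
        params = SequenceParams(5.0, 15.0, 300.0, 950.0, 33)
        assert mzss_ir(params, TissueState(400.0, 0.0)) == 0.0
        assert mzss_ir(params, TissueState(400.0, 3.0)) == pytest.approx(
            3.0 * mzss_ir(params, TissueState(400.0, 1.0)), rel=1e-12)


class TestNoInversionModel:
    def test_short_t1_full_recovery(self, swine_protocol):
        assert mzss_noinv(swine_protocol, TissueState(1e-3, 1.0)) == pytest.approx(1.0)

    def test_zero_flip_equilibrium_guarded(self):
        params = SequenceParams(3.9, 1e-9, 300.0, 1000.0, 37)
        assert mzss_noinv(params, TissueState(400.0, 1.0)) == pytest.approx(
            1.0, abs=1e-6)

    def test_frozen_oracle_value(self, swine_protocol):
        assert mzss_noinv(swine_protocol, TissueState(400.0, 1.0)) == pytest.approx(
            0.924511, abs=1e-5)


class TestT1Weighting:
    @pytest.mark.parametrize("rr", [750.0, 800.0, 900.0, 950.0])
    def test_strictly_decreasing_on_grid(self, rr):
        # monotonicity is what guarantees a one-to-one signal-T1 relation;
        # the signed signal crosses zero only above the post-contrast range
        # (near T1 ~ 780 ms for RR = 900 ms)
        params = SequenceParams(5.0, 15.0, 300.0, rr, 33)
        grid = np.arange(100.0, 800.1, 2.5)
        f = np.asarray(f_weight(params, grid))
        assert np.all(np.diff(f) < 0)
        post_contrast = (grid >= 200.0) & (grid <= 600.0)
        assert np.all(f[post_contrast] > 0)

    def test_frozen_values(self):
        p950 = SequenceParams(5.0, 15.0, 300.0, 950.0, 33)
        p750 = SequenceParams(5.0, 15.0, 300.0, 750.0, 33)
        assert f_weight(p950, 500.0) == pytest.approx(0.070527, abs=1e-5)
        assert f_weight(p750, 280.0) == pytest.approx(0.394855, abs=1e-5)


class TestImperfectInversion:
    def test_reduces_to_perfect_at_beta_one(self, accuracy_protocol):
        grid = np.arange(100.0, 800.1, 2.5)
        np.testing.assert_allclose(f_imperfect(accuracy_protocol, grid),
                                   f_weight(accuracy_protocol, grid), rtol=1e-12)

    def test_matches_modified_oracle(self, accuracy_protocol):
        import dataclasses
        params = dataclasses.replace(accuracy_protocol, inversion_factor=0.92)
        for t1 in (200.0, 300.0, 450.0, 600.0):
            oracle = bloch_recursion_oracle(params, TissueState(t1, 1.0))
            assert abs(f_imperfect(params, t1) - oracle) < 1e-9

    def test_weaker_inversion_raises_signal(self, accuracy_protocol):
        import dataclasses
        params = dataclasses.replace(accuracy_protocol, inversion_factor=0.92)
        grid = np.arange(200.0, 600.1, 25.0)
        assert np.all(np.asarray(f_imperfect(params, grid))
                      > np.asarray(f_weight(accuracy_protocol, grid)))


class TestDerivative:
    def test_negative_over_post_contrast_range(self, precision_protocol,
                                               accuracy_protocol):
        grid = np.arange(150.0, 750.1, 10.0)
        for params in (precision_protocol, accuracy_protocol):
            assert np.all(np.asarray(f_prime(params, grid)) < 0)

    def test_magnitude_decreasing_in_t1(self, precision_protocol):
        grid = np.arange(200.0, 600.1, 10.0)
        mag = np.abs(np.asarray(f_prime(precision_protocol, grid)))
        assert np.all(np.diff(mag) < 0)

    def test_frozen_value(self, precision_protocol):
        # frozen from the oracle-validated f; finite difference h = 1 ms
        assert f_prime(precision_protocol, 500.0) == pytest.approx(
            -6.944e-4, rel=1e-3)


class TestParameterValidation:
    def test_rejects_timing_overflow(self):
        with pytest.raises(ParameterError):
            SequenceParams(tr_ms=5.0, flip_deg=15.0, ti_ms=300.0, rr_ms=400.0,
                           n_views=33)

    @pytest.mark.parametrize("field,value", [
        ("tr_ms", -1.0), ("flip_deg", 95.0), ("ti_ms", 0.0),
        ("inversion_factor", 0.0), ("inversion_factor", 1.2), ("n_views", 0),
    ])
    def test_rejects_out_of_domain_fields(self, field, value):
        kwargs = dict(tr_ms=5.0, flip_deg=15.0, ti_ms=300.0, rr_ms=900.0,
                      n_views=33, inversion_factor=1.0)
        kwargs[field] = value
        with pytest.raises(ParameterError):
            SequenceParams(**kwargs)

    def test_g_noinv_recovers_with_short_t1(self, swine_protocol):
        assert g_noinv(swine_protocol, 1.0) == pytest.approx(1.0, abs=1e-12)
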