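"""Dipolar (BPP) relaxation rates: forward evaluation and inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emulrelax import BPPContext, r1_bpp, r2_bpp, ratio_r2_r1, tau_c_from_ratio, tau_c_from_r1
from emulrelax.bpp import (
    BracketingError,
    InfeasibleRateError,
    MissingPrefactorError,
    NoiseInconsistentRatioWarning,
    clamp_ratio,
    r1_argmax_omega_tau,
)
from emulrelax.constants import dipolar_prefactor


class TestContext:
    def test_angular_frequency_definition(self):
        ctx = BPPContext(larmor_frequency_hz=15e6)
        assert ctx.angular_frequency == pytest.approx(2 * math.pi * 15e6, rel=1e-12)

    def test_default_frequency_is_15_mhz(self):
        assert BPPContext().larmor_frequency_hz == 15e6

    def test_prefactor_from_r0_consistency(self):
        ctx = BPPContext.from_r0(1.8e-10)
        assert ctx.dipolar_prefactor_K == pytest.approx(
            dipolar_prefactor(1.8e-10), rel=1e-9
        )

    def test_inconsistent_k_and_r0_rejected(self):
        k = dipolar_prefactor(1.8e-10)
        with pytest.raises(ValueError, match="inconsistent"):
            BPPContext(dipolar_prefactor_K=2 * k, r0=1.8e-10)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            BPPContext(larmor_frequency_hz=0.0)

    def test_missing_prefactor_names_ratio_route(self, ctx_bare):
        with pytest.raises(MissingPrefactorError, match="ratio"):
            r1_bpp(1e-9, ctx_bare)


class TestForwardRates:
    def test_extreme_narrowing_r1(self, ctx_unit):
        # w*tau = 1e-6: both rates collapse to (3/2) K tau
        tau = 1e-6 / ctx_unit.angular_frequency
        assert r1_bpp(tau, ctx_unit) == pytest.approx(1.5 * tau, rel=1e-6)

    def test_extreme_narrowing_ratio_unity(self, ctx_unit):
        tau = 1e-6 / ctx_unit.angular_frequency
        assert r2_bpp(tau, ctx_unit) / r1_bpp(tau, ctx_unit) == pytest.approx(1.0, rel=1e-6)

    def test_r1_maximum_at_brute_force_location(self, ctx_unit):
        # independent oracle: dense log-grid search over tau_c
        taus = np.geomspace(1e-12, 1e-5, 200_000)
        rates = np.array([r1_bpp(t, ctx_unit) for t in taus])
        x_grid = ctx_unit.angular_frequency * taus[np.argmax(rates)]
        assert x_grid == pytest.approx(0.62, abs=0.01)
        assert r1_argmax_omega_tau() == pytest.approx(x_grid, rel=1e-4)

    def test_r1_dispersion_with_frequency(self, ctx_unit):
        # at w*tau >= 1, doubling the frequency lowers R1
        ctx2 = BPPContext(larmor_frequency_hz=30e6, dipolar_prefactor_K=1.0)
        for x in np.linspace(1.0, 50.0, 20):
            tau = x / ctx_unit.angular_frequency
            assert r1_bpp(tau, ctx2) < r1_bpp(tau, ctx_unit)

    def test_r2_secular_limit(self, ctx_unit):
        tau = 1e3 / ctx_unit.angular_frequency
        assert r2_bpp(tau, ctx_unit) == pytest.approx((9 / 20) * tau, rel=0.01)

    def test_r2_strictly_increasing(self, ctx_unit):
        taus = np.geomspace(1e-12, 1e-6, 500)
        rates = np.array([r2_bpp(t, ctx_unit) for t in taus])
        assert np.all(np.diff(rates) > 0)

    def test_r2_at_least_r1_with_narrowing_equality(self, ctx_unit):
        taus = np.geomspace(1e-12, 1e-6, 1000)
        for tau in taus:
            r1, r2 = r1_bpp(tau, ctx_unit), r2_bpp(tau, ctx_unit)
            assert r2 >= r1
            if ctx_unit.angular_frequency * tau < 1e-3:
                assert r2 == pytest.approx(r1, rel=1e-3)

    def test_nonpositive_tau_rejected(self, ctx_unit):
        with pytest.raises(ValueError):
            r1_bpp(0.0, ctx_unit)


class TestRatio:
    def test_value_at_omega_tau_one(self, ctx_bare):
        # (1/2)(3 + 5/2 + 2/5) / (1/2 + 4/5) = 2.2692...
        tau = 1.0 / ctx_bare.angular_frequency
        assert ratio_r2_r1(tau, ctx_bare) == pytest.approx(2.269, abs=1e-3)

    def test_strictly_increasing_on_log_grid(self, ctx_bare):
        taus = np.geomspace(1e-12, 1e-6, 1000)
        vals = np.array([ratio_r2_r1(t, ctx_bare) for t in taus])
        assert np.all(np.diff(vals) > 0)
        assert np.all(vals >= 1.0)

    def test_k_independence_bitwise(self):
        # same code path regardless of K: values identical to the bit
        for tau in np.geomspace(1e-11, 1e-7, 50):
            a = ratio_r2_r1(tau, BPPContext(dipolar_prefactor_K=1.0))
            b = ratio_r2_r1(tau, BPPContext(dipolar_prefactor_K=1e9))
            assert a == b

    @given(st.floats(min_value=-11, max_value=-7))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_decade_monotonicity(self, log_tau):
        ctx = BPPContext()
        tau = 10.0**log_tau
        assert ratio_r2_r1(10 * tau, ctx) > ratio_r2_r1(tau, ctx)


class TestTauFromRatio:
    def test_narrowing_limit_tiny_tau(self, ctx_bare):
        tau = tau_c_from_ratio(1 + 1e-9, ctx_bare).tau_c
        assert tau < 1e-10

    def test_round_trip(self, ctx_bare):
        tau0 = 5e-9
        ratio = ratio_r2_r1(tau0, ctx_bare)
        tau = tau_c_from_ratio(ratio, ctx_bare).tau_c
        assert tau == pytest.approx(tau0, rel=1e-8)

    def test_omega_tau_one_inverse(self, ctx_bare):
        tau = tau_c_from_ratio(2.269, ctx_bare).tau_c
        assert tau == pytest.approx(1.06e-8, rel=1e-2)

    def test_grid_oracle_agreement(self, ctx_bare):
        # exhaustive argmin on a fine grid vs the bisection root
        taus = np.geomspace(1e-12, 1e-6, 6 * 10_000 + 1)
        vals = np.array([ratio_r2_r1(t, ctx_bare) for t in taus])
        step = math.log(taus[1] / taus[0])
        for target in np.geomspace(1.01, 40.0, 12):
            grid_tau = taus[np.argmin(np.abs(vals - target))]
            root = tau_c_from_ratio(float(target), ctx_bare).tau_c
            assert abs(math.log(root / grid_tau)) <= step

    def test_marginally_low_ratio_clamped_and_flagged(self, ctx_bare):
        with pytest.warns(NoiseInconsistentRatioWarning):
            ct = tau_c_from_ratio(0.97, ctx_bare)
        assert ct.clamped
        assert ct.tau_c < 1e-10

    def test_pathological_ratio_aborts(self, ctx_bare):
        with pytest.raises(ValueError, match="inconsistent"):
            tau_c_from_ratio(0.5, ctx_bare)

    def test_clamp_policy_boundaries(self):
        val, flag = clamp_ratio(0.95)
        assert flag and val == pytest.approx(1.0, abs=1e-8)
        val, flag = clamp_ratio(1.5)
        assert not flag and val == 1.5

    def test_bad_bracket_raises(self, ctx_bare):
        with pytest.raises(BracketingError):
            tau_c_from_ratio(2.0, ctx_bare, bracket=(1e-14, 1e-12))


class TestTauFromR1:
    def test_fast_branch_round_trip(self, ctx_unit):
        tau0 = 0.1 / ctx_unit.angular_frequency
        r1 = r1_bpp(tau0, ctx_unit)
        assert tau_c_from_r1(r1, ctx_unit, "fast").tau_c == pytest.approx(tau0, rel=1e-8)

    def test_slow_branch_is_distinct_root(self, ctx_unit):
        tau0 = 0.1 / ctx_unit.angular_frequency
        r1 = r1_bpp(tau0, ctx_unit)
        slow = tau_c_from_r1(r1, ctx_unit, "slow").tau_c
        assert slow * ctx_unit.angular_frequency > 0.62
        assert r1_bpp(slow, ctx_unit) == pytest.approx(r1, rel=1e-8)

    def test_infeasible_rate_reports_maximum(self, ctx_unit):
        tau_max = r1_argmax_omega_tau() / ctx_unit.angular_frequency
        r1_max = r1_bpp(tau_max, ctx_unit)
        with pytest.raises(InfeasibleRateError, match="maximum"):
            tau_c_from_r1(1.001 * r1_max, ctx_unit, "fast")

    def test_branch_must_be_explicit(self, ctx_unit):
        with pytest.raises(ValueError, match="branch"):
            tau_c_from_r1(1e-3, ctx_unit, "auto")

    def test_requires_prefactor(self, ctx_bare):
        with pytest.raises(MissingPrefactorError):
            tau_c_from_r1(1.0, ctx_bare, "fast")
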