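import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.special import gammaln

from sdssa import (DelayState, MMParams, alpha_of, beta_of, coeff_C1,
                   coeff_C2, harmonic_means, mm_effective_rate, state_delay,
                   tau2_closed_form, tau2_robust)
from sdssa.delay_formula import (DelayDomainError, EPS_DELAY,
                                 _tau2_self_consistent)

# pathway parameters of the elongation steps 2..6
MM = MMParams(V=(38.27, 73.44, 35.84, 9.31, 2.08),
              K=(12185600.0, 11852800.0, 9164800.0, 6476800.0, 2073600.0))


def bisect_delay(C: float, n: int, k: float) -> float:
    """Independent root of z^n e^{-z/2} = C on the physical branch z < 2n."""
    g = lambda z: n * np.log(z) - z / 2.0 - np.log(C)
    assert g(2.0 * n) > 0, "C outside the physical branch"
    return brentq(g, 1e-12, 2.0 * n, xtol=1e-15, rtol=1e-15) / k


class TestCoefficients:
    @pytest.mark.parametrize("x1, y, n, expected",
                             [(20, 0, 9, 20.0), (10, 9, 10, 9.0),
                              (2, 8, 5, 0.0)])
    def test_c1_examples(self, x1, y, n, expected):
        assert coeff_C1(x1, y, n) == pytest.approx(expected)

    @pytest.mark.parametrize("x1, expected", [(10, 4.0), (5, 4.75),
                                              (1000000, 3.2500075)])
    def test_alpha_examples(self, x1, expected):
        assert alpha_of(x1) == pytest.approx(expected)

    @pytest.mark.parametrize("x1, expected", [(10, 93.8), (1, 20.0),
                                              (50, 421.8)])
    def test_beta_examples(self, x1, expected):
        assert beta_of(x1) == pytest.approx(expected)

    @pytest.mark.parametrize("n", [3, 5, 9])
    @pytest.mark.parametrize("x1", [2, 8, 25])
    def test_c2_boundary_identity_at_beta(self, x1, n):
        """C2 equals -1/y exactly where it crosses the degenerate locus."""
        beta = beta_of(x1) * (n - 1) / 8.0
        assert coeff_C2(x1, beta, n) == pytest.approx(-1.0 / beta, abs=1e-12)

    def test_c2_monotone_decreasing_in_y(self):
        for x1 in (5, 20, 50):
            ys = np.arange(1, 12 * x1)
            c2 = np.array([coeff_C2(x1, float(y), 9) for y in ys])
            assert np.all(np.diff(c2) < 0)
        assert coeff_C2(20, 5, 9) > coeff_C2(20, 30, 9)

    def test_c2_larger_for_larger_x1_at_moderate_y(self):
        # at a fixed moderate y the smaller pool has the smaller C2
        assert coeff_C2(5, 30, 9) < coeff_C2(20, 30, 9) < coeff_C2(50, 30, 9)

    def test_c2_undefined_for_y_zero(self):
        with pytest.raises(ValueError):
            coeff_C2(10, 0, 9)


class TestTau2ClosedForm:
    def test_matches_bisection_oracle_y0(self):
        x1, k, n = 20, 0.1, 9
        C = np.exp(float(gammaln(n + 1))) / x1
        oracle = bisect_delay(C, n, k)
        closed = tau2_closed_form(DelayState(x1, 0, k, n))
        assert closed == pytest.approx(oracle, rel=1e-10)

    def test_matches_bisection_oracle_general_y(self):
        for x1, y, k, n in [(20, 10, 0.5, 9), (8, 3, 2.0, 5), (40, 60, 0.05, 9)]:
            C1 = coeff_C1(x1, y, n)
            C = (1 + coeff_C2(x1, y, n) * y) * np.exp(float(gammaln(n + 1))) / C1
            oracle = bisect_delay(C, n, k)
            closed = tau2_closed_form(DelayState(x1, y, k, n))
            assert closed == pytest.approx(oracle, rel=1e-10)

    def test_k_scaling_invariance(self):
        # the delay equation depends on k and tau2 only through k*tau2
        for y in (0, 12):
            ref = tau2_closed_form(DelayState(30, y, 1.0, 9))
            for k in (0.05, 0.1, 0.5, 1.0):
                tau = tau2_closed_form(DelayState(30, y, k, 9))
                assert tau * k == pytest.approx(ref, rel=1e-12)

    def test_delay_decreases_with_pool_size(self):
        assert tau2_closed_form(DelayState(5, 0, 0.1, 9)) > \
            tau2_closed_form(DelayState(40, 0, 0.1, 9))

    def test_delay_increases_with_queue(self):
        taus = [tau2_closed_form(DelayState(20, y, 0.1, 9))
                for y in (0, 5, 15, 30)]
        assert np.all(np.diff(taus) > 0)

    def test_degenerate_c1_branch(self):
        # y = (n-1)*x1 makes C1 = 0: tau2 = (n-1)(1 + 1/y)/k exactly
        x1, n, k = 4, 9, 0.25
        y = (n - 1) * x1
        tau = tau2_closed_form(DelayState(x1, y, k, n))
        assert tau == pytest.approx((n - 1) * (1 + 1 / y) / k, rel=1e-12)

    def test_x1_zero_rejected(self):
        with pytest.raises(ValueError):
            tau2_closed_form(DelayState(0, 3, 1.0, 9))

    def test_infeasible_state_raises_domain_error(self):
        # between the C1=0 locus (y=8*x1) and beta the fitted C2 yields C<0
        with pytest.raises(DelayDomainError):
            tau2_closed_form(DelayState(2, 18, 1.0, 9))

    def test_robust_fallback_is_finite_everywhere(self):
        for x1 in (1, 2, 5, 20):
            for y in (0, 1, x1, 8 * x1, 8 * x1 + 3, 12 * x1):
                tau = tau2_robust(DelayState(x1, y, 0.5, 9))
                assert np.isfinite(tau) and 0 < tau < 1e4

    def test_self_consistent_mode_solves_its_equation(self):
        state = DelayState(20, 10, 0.1, 9)
        tau = _tau2_self_consistent(state)
        z = tau * state.k
        lhs = coeff_C1(20, 10, 9) * np.exp(
            9 * np.log(z) - z / 2 - float(gammaln(10)))
        rhs = 1 + (1 - z / 8) * 10
        assert lhs == pytest.approx(rhs, abs=1e-8)


class TestStateDelay:
    def test_tau1_zero_returns_tau2(self):
        state = DelayState(20, 0, 0.1, 9)
        assert state_delay(state, 0.0) == tau2_closed_form(state)

    def test_floor_when_tau1_exceeds_tau2(self):
        state = DelayState(20, 0, 0.1, 9)
        assert state_delay(state, 1e6) == EPS_DELAY

    def test_stochastic_mode_has_requested_mean(self, rng):
        state = DelayState(20, 0, 0.1, 9)
        tau2 = tau2_closed_form(state)
        draws = np.array([state_delay(state, 0.0, rng, stochastic=True)
                          for _ in range(4000)])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - tau2) < 3.5 * se


class TestMichaelisMentenLumping:
    def test_harmonic_mean_of_equal_entries(self):
        p = MMParams(V=(3.0,) * 5, K=(7.0,) * 5)
        assert harmonic_means(p) == (pytest.approx(3.0), pytest.approx(7.0))

    def test_pathway_harmonic_means(self):
        vbar, kbar = harmonic_means(MM)
        assert vbar == pytest.approx(7.624, abs=2e-3)
        assert kbar == pytest.approx(5.481e6, rel=1e-3)

    def test_effective_rate_is_harmonic_mean_of_step_rates(self):
        V = np.array(MM.V)
        K = np.array(MM.K)
        for U in (0.0, 100.0, 5e6):
            direct = 5.0 / np.sum((K + U / 5.0) / V)
            assert mm_effective_rate(U, MM) == pytest.approx(direct, rel=1e-12)

    def test_pseudo_first_order_regime(self):
        # U far below the K scale leaves the rate at its U -> 0 limit
        assert mm_effective_rate(100.0, MM) == \
            pytest.approx(mm_effective_rate(0.0, MM), rel=1e-4)

    def test_rate_decreases_with_load(self):
        assert mm_effective_rate(2e6, MM) < mm_effective_rate(1e6, MM)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MMParams(V=(1.0, -2.0), K=(1.0, 1.0))
        with pytest.raises(ValueError):
            mm_effective_rate(-1.0, MM)
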