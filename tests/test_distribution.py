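"""Core distribution functions: hand values, identities, quadrature oracles."""

import numpy as np
import pytest

import nowiw as nw
from nowiw.distribution import (
    characteristic_function,
    incomplete_moment,
    inequality_curves,
    inverse_weibull_baseline,
    now_family_cdf,
    pwm,
    quantile_paper,
)

XGRID = np.array([0.3, 0.5, 0.8, 1.0, 1.5, 2.0, 3.0, 5.0, 10.0])


def brute_trapezoid(fn, n_nodes=1_000_001):
    """Independent dense-trapezoid integral of fn over (0, inf), via x = u/(1-u)."""
    u = np.linspace(1e-9, 1 - 1e-9, n_nodes)
    x = u / (1 - u)
    return np.trapezoid(fn(x) / (1 - u) ** 2, u)


class TestPointValues:
    """Hand-evaluated values at eta = zeta = k = n = 1, x = 1."""

    def test_cdf(self, unit_params):
        # H = e^-1, g = -H log(1-H) = 0.1687372, F = 1 - e^-g
        assert nw.cdf(1.0, unit_params) == pytest.approx(0.15527, abs=5e-6)

    def test_pdf(self, unit_params):
        # bracket = H/(1-H) - log(1-H) = 1.040652
        assert nw.pdf(1.0, unit_params) == pytest.approx(0.32339, abs=5e-6)

    def test_sf_and_hazard(self, unit_params):
        assert nw.sf(1.0, unit_params) == pytest.approx(0.84473, abs=5e-6)
        # hazard = pdf/sf = 0.32339/0.84473 = 0.382834
        assert nw.hazard(1.0, unit_params) == pytest.approx(0.38283, abs=5e-6)

    def test_generator_with_iw_baseline_matches(self, unit_params):
        base = inverse_weibull_baseline(1.0, 1.0)
        got = now_family_cdf(1.0, {"eta": 1.0, "zeta": 1.0}, base)
        assert got == pytest.approx(0.15527, abs=5e-6)


class TestIdentities:
    def test_generator_reduction_equals_direct_cdf(self, param_grid):
        for p in param_grid:
            base = inverse_weibull_baseline(p.k, p.n)
            fam = now_family_cdf(XGRID, {"eta": p.eta, "zeta": p.zeta}, base)
            np.testing.assert_allclose(fam, nw.cdf(XGRID, p), atol=1e-14)

    def test_sf_plus_cdf_is_one(self, param_grid):
        for p in param_grid:
            np.testing.assert_allclose(nw.sf(XGRID, p) + nw.cdf(XGRID, p), 1.0,
                                       atol=1e-12)

    def test_hazard_times_sf_is_pdf(self, param_grid):
        for p in param_grid:
            np.testing.assert_allclose(nw.hazard(XGRID, p) * nw.sf(XGRID, p),
                                       nw.pdf(XGRID, p), atol=1e-10)

    def test_cdf_monotone_with_support_limits(self, param_grid):
        for p in param_grid:
            vals = nw.cdf(XGRID, p)
            assert np.all(np.diff(vals) >= 0)
            assert nw.cdf(1e-12, p) == pytest.approx(0.0, abs=1e-12)
            # upper limit through the quantile: some zeta < 1 sets carry tail
            # mass beyond float range, so probe at a representable point
            x_hi = nw.quantile(1 - 1e-8, p)
            if np.isfinite(x_hi):
                assert nw.cdf(x_hi, p) == pytest.approx(1.0, abs=1e-6)
            else:
                assert nw.cdf(1e290, p) < 1.0  # mass genuinely beyond doubles

    def test_pdf_matches_cdf_derivative(self, finite_mean_params):
        h = 1e-6
        x = XGRID
        num = (nw.cdf(x + h, finite_mean_params) - nw.cdf(x - h, finite_mean_params)) / (2 * h)
        np.testing.assert_allclose(nw.pdf(x, finite_mean_params), num, rtol=1e-6)

    def test_normalization_on_grid(self, param_grid):
        # integrate the density up to the 1 - 1e-9 quantile and require the
        # mass to equal the cdf there to 1e-8; for zeta >= 1 that point covers
        # essentially all mass, and for the extreme zeta < 1 tails (mass beyond
        # float range) it still pins the density against the cdf
        from scipy.integrate import quad
        for p in param_grid:
            x_lo = nw.quantile(1e-12, p)
            x_hi = min(nw.quantile(1 - 1e-9, p), 1e12)
            # integrate in y = log x: heavy tails are spread evenly there
            val, _ = quad(lambda y: nw.pdf(np.exp(y), p) * np.exp(y),
                          np.log(x_lo), np.log(x_hi), limit=300)
            assert val == pytest.approx(nw.cdf(x_hi, p), abs=1e-8)

    def test_domain_errors(self, unit_params):
        with pytest.raises(ValueError):
            nw.cdf(-1.0, unit_params)
        with pytest.raises(ValueError):
            nw.pdf(0.0, unit_params)
        with pytest.raises(ValueError):
            nw.NOWIWParams(1.0, 0.0, 1.0, 1.0)


class TestQuantile:
    def test_inverse_of_hand_value(self, unit_params):
        assert nw.quantile(0.15527, unit_params) == pytest.approx(1.0, abs=1e-4)

    def test_round_trips(self, finite_mean_params):
        for x in (0.5, 1.0, 2.0, 5.0):
            assert nw.quantile(nw.cdf(x, finite_mean_params), finite_mean_params) == \
                pytest.approx(x, rel=1e-6)
        for p in (0.01, 0.3, 0.5, 0.9, 0.999):
            assert nw.cdf(nw.quantile(p, finite_mean_params), finite_mean_params) == \
                pytest.approx(p, abs=1e-10)

    def test_strictly_increasing_and_support_limits(self, param_grid):
        ps = np.linspace(0.01, 0.99, 25)
        for p in param_grid[:4]:
            q = nw.quantile(ps, p)
            assert np.all(np.diff(q) > 0)
            assert nw.quantile(1e-10, p) < nw.quantile(0.01, p)
            hi = nw.quantile(1 - 1e-12, p)
            if np.isfinite(hi):  # extreme zeta < 1 quantiles exceed float range
                assert hi > nw.quantile(0.99, p)

    def test_domain_error(self, unit_params):
        with pytest.raises(ValueError):
            nw.quantile(0.0, unit_params)
        with pytest.raises(ValueError):
            nw.quantile(1.0, unit_params)


class TestQuantilePaper:
    def test_branch_domain_violation_is_flagged_not_raised(self, unit_params):
        out = quantile_paper(0.1, unit_params)
        assert out["status"] in ("branch-domain-violation", "invalid-intermediate", "ok")
        if out["status"] != "ok":
            assert np.isnan(out["value"])

    def test_consistency_guard_when_residual_small(self, param_grid):
        # whenever the closed form happens to invert the cdf, it must agree
        # with the numeric quantile; otherwise the residual exposes it
        for p in param_grid[:6]:
            for prob in (0.1, 0.5, 0.9):
                out = quantile_paper(prob, p)
                if out["status"] == "ok" and out["residual"] < 1e-8:
                    assert out["value"] == pytest.approx(
                        nw.quantile(prob, p), rel=1e-6)


class TestMoments:
    def test_divergence_at_polynomial_tail(self, unit_params):
        # zeta = 1 gives survival ~ x^-(eta n) = x^-1, so E[X] diverges
        assert not nw.moment(1, unit_params).finite

    def test_all_moments_diverge_below_zeta_one(self):
        p = nw.NOWIWParams(1.0, 0.7, 1.0, 2.0)
        assert not nw.moment(1, p).finite

    def test_matches_brute_force(self, finite_mean_params):
        m1 = nw.moment(1, finite_mean_params)
        ref = brute_trapezoid(lambda x: x * nw.pdf(x, finite_mean_params))
        assert m1.finite and m1.value == pytest.approx(ref, rel=1e-6)

    def test_jensen(self, finite_mean_params):
        m1, m2 = nw.moment(1, finite_mean_params), nw.moment(2, finite_mean_params)
        assert m2.value >= m1.value ** 2

    def test_summary_identities_and_skew_sign(self, finite_mean_params):
        s = nw.summary(finite_mean_params)
        m1, m2 = nw.moment(1, finite_mean_params), nw.moment(2, finite_mean_params)
        assert s.variance == pytest.approx(m2.value - m1.value ** 2, abs=1e-8)
        assert s.skewness > 0  # right-skewed lifetime model

    def test_summary_divergence_propagates(self):
        # zeta = 1, eta*n = 3: moments 1,2 finite, 3 and 4 divergent
        p = nw.NOWIWParams(3.0, 1.0, 1.0, 1.0)
        s = nw.summary(p)
        assert s.existence_flags[2] and not s.existence_flags[4]
        assert np.isfinite(s.variance)
        assert np.isnan(s.kurtosis) and np.isnan(s.skewness)


class TestIncompleteMomentAndCurves:
    def test_limits_and_monotonicity(self, finite_mean_params):
        p = finite_mean_params
        assert incomplete_moment(1, 1e-6, p) == pytest.approx(0.0, abs=1e-10)
        ys = [0.5, 1.0, 2.0, 5.0, 20.0]
        vals = [incomplete_moment(1, y, p) for y in ys]
        assert np.all(np.diff(vals) >= 0)
        # brute-force oracle on the truncated range
        y99 = nw.quantile(0.99, p)
        u99 = y99 / (1 + y99)
        u = np.linspace(1e-9, u99, 400_001)
        x = u / (1 - u)
        ref = np.trapezoid(x * nw.pdf(x, p) / (1 - u) ** 2, u)
        assert incomplete_moment(1, y99, p) == pytest.approx(ref, rel=1e-6)
        # convergence to the full moment
        near_full = incomplete_moment(1, nw.quantile(0.9999, p), p)
        assert near_full == pytest.approx(nw.moment(1, p).value, rel=0.01)

    def test_inequality_curves(self, finite_mean_params):
        p = finite_mean_params
        med = nw.quantile(0.5, p)
        out = inequality_curves(med, p)
        assert out["finite"]
        assert out["bonferroni"] * nw.cdf(med, p) == pytest.approx(out["lorenz"], abs=1e-10)
        assert out["lorenz"] < 0.5  # Lorenz curve below the diagonal at the median
        far = inequality_curves(nw.quantile(0.9999, p), p)
        assert far["lorenz"] == pytest.approx(1.0, abs=0.01)

    def test_divergent_mean_flags(self, unit_params):
        out = inequality_curves(1.0, unit_params)
        assert not out["finite"] and np.isnan(out["lorenz"])


class TestPWM:
    def test_q_zero_reduces_to_moment(self, finite_mean_params):
        assert pwm(1, 0, finite_mean_params).value == pytest.approx(
            nw.moment(1, finite_mean_params).value, rel=1e-8)

    def test_decreasing_in_q_and_oracle(self, finite_mean_params):
        p = finite_mean_params
        v10, v11 = pwm(1, 0, p).value, pwm(1, 1, p).value
        assert v11 <= v10
        ref = brute_trapezoid(lambda x: x * nw.pdf(x, p) * nw.cdf(x, p))
        assert v11 == pytest.approx(ref, rel=1e-6)


class TestEntropy:
    def test_shared_j_and_determinism(self, finite_mean_params):
        outs = {kind: nw.entropy(kind, 2.0, finite_mean_params)
                for kind in ("renyi", "tsallis", "havrda_charvat", "arimoto")}
        js = {o["J"] for o in outs.values()}
        assert len(js) == 1  # all four transforms of one J(c)
        again = nw.entropy("renyi", 2.0, finite_mean_params)
        assert again == outs["renyi"]

    def test_tsallis_order_two(self, finite_mean_params):
        out = nw.entropy("tsallis", 2.0, finite_mean_params)
        assert out["value"] == pytest.approx(1.0 - out["J"], abs=1e-12)
        assert out["value"] < 1.0

    def test_j_matches_brute_force(self, finite_mean_params):
        out = nw.entropy("renyi", 2.0, finite_mean_params)
        ref = brute_trapezoid(lambda x: nw.pdf(x, finite_mean_params) ** 2)
        assert out["J"] == pytest.approx(ref, rel=1e-6)

    def test_invalid_order(self, finite_mean_params):
        with pytest.raises(ValueError):
            nw.entropy("renyi", 1.0, finite_mean_params)
        with pytest.raises(ValueError):
            nw.entropy("nope", 2.0, finite_mean_params)


class TestPropertyBased:
    from hypothesis import given, settings, strategies as st

    pos = st.floats(min_value=0.3, max_value=3.0, allow_nan=False)

    @given(eta=pos, zeta=pos, k=pos, n=pos, p=st.floats(min_value=0.01, max_value=0.99))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_quantile_cdf_round_trip_property(self, eta, zeta, k, n, p):
        params = nw.NOWIWParams(eta, zeta, k, n)
        assert nw.cdf(nw.quantile(p, params), params) == pytest.approx(p, abs=1e-9)

    @given(eta=pos, zeta=pos, k=pos, n=pos,
           x=st.floats(min_value=0.05, max_value=50.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_function_identities_property(self, eta, zeta, k, n, x):
        params = nw.NOWIWParams(eta, zeta, k, n)
        assert nw.sf(x, params) + nw.cdf(x, params) == pytest.approx(1.0, abs=1e-12)
        assert nw.hazard(x, params) * nw.sf(x, params) == pytest.approx(
            nw.pdf(x, params), abs=1e-10)


class TestCharacteristicFunction:
    def test_at_zero_and_conjugate_symmetry(self, finite_mean_params):
        assert characteristic_function(0.0, finite_mean_params) == 1.0 + 0.0j
        plus = characteristic_function(0.5, finite_mean_params)
        minus = characteristic_function(-0.5, finite_mean_params)
        assert abs(plus - np.conj(minus)) < 1e-8
        assert abs(plus) <= 1.0 + 1e-12

    def test_against_monte_carlo(self, finite_mean_params):
        x = nw.rvs(finite_mean_params, 1_000_000, seed=2024)
        draws = np.exp(1j * 1.0 * x)
        mc = draws.mean()
        se = np.std(draws.real) / np.sqrt(x.size) + 1j * np.std(draws.imag) / np.sqrt(x.size)
        phi = characteristic_function(1.0, finite_mean_params)
        assert abs(phi.real - mc.real) < 3 * se.real
        assert abs(phi.imag - mc.imag) < 3 * se.imag
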