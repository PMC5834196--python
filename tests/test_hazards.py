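"""Hazard families, frailty marginals and the rate of aging."""
import numpy as np
import pytest
from scipy.integrate import quad

import allosurv as al
from allosurv.hazards import FAMILIES

PARAM_SETS = [
    ("gompertz", {"a": 1e-4, "b": 0.09}),
    ("gompertz_makeham", {"a": 2e-4, "b": 0.07, "c": 0.01}),
    ("weibull", {"lam": 0.01, "k": 1.4}),
    ("weibull", {"lam": 0.05, "k": 0.96}),
    ("weibull_makeham", {"lam": 0.02, "k": 1.2, "c": 0.005}),
]


class TestClosedForms:
    def test_weibull_k1_is_flat(self):
        for x in (1.0, 10.0, 80.0):
            assert al.hazard("weibull", {"lam": 0.01, "k": 1.0}, x) == pytest.approx(0.01)

    def test_gompertz_at_zero(self):
        assert al.hazard("gompertz", {"a": 0.001, "b": 0.1}, 0.0) == pytest.approx(0.001)

    def test_weibull_example(self):
        assert al.hazard("weibull", {"lam": 2.0, "k": 2.0}, 3.0) == pytest.approx(12.0)

    def test_exponential_cumhaz(self):
        assert al.cumulative_hazard("weibull", {"lam": 0.5, "k": 1.0}, 2.0) == pytest.approx(1.0)

    def test_gompertz_small_b_limit(self):
        a, x = 0.01, 50.0
        val = al.cumulative_hazard("gompertz", {"a": a, "b": 1e-12}, x)
        assert val == pytest.approx(a * x, rel=1e-9)
        assert al.cumulative_hazard("gompertz", {"a": a, "b": 0.0}, x) == a * x

    def test_survival_basics(self):
        for fam, params in PARAM_SETS:
            assert al.survival(fam, params, 0.0) == pytest.approx(1.0)
        assert al.survival("weibull", {"lam": 1.0, "k": 1.0}, 1.0) == pytest.approx(np.exp(-1))

    def test_weibull_singularity_guard(self):
        with pytest.raises(ValueError):
            al.hazard("weibull", {"lam": 1.0, "k": 0.8}, 0.0)


class TestConsistency:
    @pytest.mark.parametrize("family,params", PARAM_SETS)
    def test_cumhaz_matches_quadrature(self, family, params):
        """Closed-form Lambda equals the numeric integral of the hazard."""
        for x in (2.5, 30.0, 75.0):
            numeric, _ = quad(lambda u: al.hazard(family, params, u), 0.0, x, limit=200)
            closed = al.cumulative_hazard(family, params, x)
            assert closed == pytest.approx(numeric, rel=1e-8)

    @pytest.mark.parametrize("family,params", PARAM_SETS)
    def test_survival_equals_exp_minus_cumhaz(self, family, params):
        x = np.linspace(0.5, 90, 40)
        np.testing.assert_allclose(
            al.survival(family, params, x),
            np.exp(-al.cumulative_hazard(family, params, x)),
            rtol=0,
        )

    @pytest.mark.parametrize("family,params", PARAM_SETS)
    def test_hazard_is_minus_dlog_survival(self, family, params):
        """h(x) = -d/dx log S(x) by central differences on [1, 90]."""
        x = np.linspace(1.0, 90.0, 25)
        h = 1e-6 * np.maximum(1.0, x)
        lo = -al.cumulative_hazard(family, params, x - h)
        hi = -al.cumulative_hazard(family, params, x + h)
        np.testing.assert_allclose(
            al.hazard(family, params, x), -(hi - lo) / (2 * h), rtol=1e-6
        )

    @pytest.mark.parametrize("family,params", PARAM_SETS)
    def test_survival_monotone(self, family, params):
        x = np.linspace(0, 100, 200)
        s = al.survival(family, params, x)
        assert np.all(np.diff(s) <= 0)


GAMMA = al.FrailtySpec("gamma", 1.0)
IG = al.FrailtySpec("inverse_gaussian", 0.8)
LOGN = al.FrailtySpec("log_normal", 0.5)


class TestFrailtyMarginals:
    def test_gamma_closed_form_example(self):
        # exponential baseline, Lambda(1) = 1, sigma2 = 1: S_m = (1+1)^-1
        s = al.frailty_marginal_survival("weibull", {"lam": 1.0, "k": 1.0}, GAMMA, 1.0)
        assert s == pytest.approx(0.5)

    def test_gamma_marginal_hazard_example(self):
        h = al.frailty_marginal_hazard("weibull", {"lam": 1.0, "k": 1.0}, GAMMA, 1.0)
        assert h == pytest.approx(0.5)

    def test_sigma2_zero_limits(self):
        """All marginal forms collapse to the baseline as sigma2 -> 0."""
        x = np.linspace(0.5, 90, 30)
        params = {"lam": 0.01, "k": 1.3}
        base_s = al.survival("weibull", params, x)
        base_h = al.hazard("weibull", params, x)
        for dist in ("gamma", "inverse_gaussian", "log_normal"):
            fr = al.FrailtySpec(dist, 1e-10)
            np.testing.assert_allclose(
                al.frailty_marginal_survival("weibull", params, fr, x), base_s, atol=1e-6
            )
            np.testing.assert_allclose(
                al.frailty_marginal_hazard("weibull", params, fr, x), base_h, atol=1e-6
            )

    @pytest.mark.parametrize("frailty", [GAMMA, IG, LOGN])
    def test_marginal_survival_bounds_baseline(self, frailty):
        """Frailty mixing raises population survival at any Lambda > 0."""
        x = np.linspace(1.0, 90, 30)
        params = {"lam": 0.02, "k": 1.2}
        assert np.all(
            al.frailty_marginal_survival("weibull", params, frailty, x)
            >= al.survival("weibull", params, x)
        )

    def test_lognormal_against_monte_carlo(self, rng):
        """Gauss-Hermite marginal matches brute-force mixing over 1e6 draws."""
        params = {"lam": 0.01, "k": 1.4}
        s2 = 0.5
        sln2 = np.log1p(s2)
        z = np.exp(rng.normal(-0.5 * sln2, np.sqrt(sln2), size=1_000_000))
        for x in (20.0, 50.0, 80.0):
            lam = al.cumulative_hazard("weibull", params, x)
            draws = np.exp(-z * lam)
            mc = draws.mean()
            mc_se = draws.std(ddof=1) / np.sqrt(len(draws))
            gh = al.frailty_marginal_survival(
                "weibull", params, al.FrailtySpec("log_normal", s2), x
            )
            assert abs(gh - mc) < 3 * mc_se

    @pytest.mark.parametrize("frailty", [GAMMA, IG, LOGN])
    def test_marginal_hazard_is_derivative(self, frailty):
        """-d/dx log S_m matches the closed/quadrature marginal hazard."""
        params = {"lam": 0.01, "k": 1.4}
        x = np.linspace(5, 90, 18)
        h = 1e-5 * x
        num = -(
            al.marginal_log_survival("weibull", params, frailty, x + h)
            - al.marginal_log_survival("weibull", params, frailty, x - h)
        ) / (2 * h)
        np.testing.assert_allclose(
            al.frailty_marginal_hazard("weibull", params, frailty, x), num, rtol=1e-5
        )


class TestRateOfAging:
    def test_gompertz_constant_b(self):
        for x in (1.0, 40.0, 90.0):
            assert al.rate_of_aging("gompertz", {"a": 1e-4, "b": 0.1}, x) == 0.1

    def test_weibull_closed_form(self):
        x = np.array([10.0, 50.0])
        np.testing.assert_array_equal(
            al.rate_of_aging("weibull", {"lam": 0.01, "k": 1.4}, x), (1.4 - 1) / x
        )

    def test_weibull_k1_flat(self):
        assert al.rate_of_aging("weibull", {"lam": 0.3, "k": 1.0}, 33.0) == 0.0

    def test_decelerating_shape_is_negative(self):
        # k = 0.96: the decelerating early-interval pattern
        assert al.rate_of_aging("weibull", {"lam": 1.47, "k": 0.96}, 45.0) < 0

    @pytest.mark.parametrize(
        "family,params,frailty",
        [
            ("gompertz_makeham", {"a": 2e-4, "b": 0.08, "c": 0.01}, al.NO_FRAILTY),
            ("weibull", {"lam": 0.01, "k": 1.4}, GAMMA),
            ("gompertz", {"a": 1e-4, "b": 0.1}, GAMMA),
        ],
    )
    def test_matches_central_difference(self, family, params, frailty):
        x = np.linspace(20, 90, 15)
        h = 1e-6 * x
        num = (
            np.log(al.frailty_marginal_hazard(family, params, frailty, x + h))
            - np.log(al.frailty_marginal_hazard(family, params, frailty, x - h))
        ) / (2 * h)
        np.testing.assert_allclose(
            al.rate_of_aging(family, params, x, frailty), num, rtol=1e-4, atol=1e-8
        )

    def test_gamma_gompertz_plateau(self):
        """Gamma-Gompertz population hazard flattens at high ages."""
        params = {"a": 1e-4, "b": 0.12}
        roa = al.rate_of_aging("gompertz", params, np.array([40.0, 110.0]), GAMMA)
        assert roa[1] < roa[0] < 0.12

    def test_requires_positive_age(self):
        with pytest.raises(ValueError):
            al.rate_of_aging("gompertz", {"a": 1e-4, "b": 0.1}, 0.0)
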