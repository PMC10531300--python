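import numpy as np
import pytest

from sfstests.linear_tests import LinearTest
from sfstests.nonlinear_tests import (MomentModel, PolynomialTest,
                                      evaluate_polynomial, fu_g_diagonal,
                                      fu_g_many, fu_g_renormalised,
                                      general_optimal, linear_wc_optimal,
                                      multiset_multiplicity, multisets_up_to,
                                      poisson_moment, poisson_moment_taylor,
                                      quadratic_sc_optimal, quadratic_wc_optimal,
                                      sc_linear_max_expectation,
                                      wc_linear_max_expectation)
from sfstests.nonlinear_tests import _solve_spd
from sfstests.simulate import sample_sfs
from sfstests.spectrum import SpectrumCounts, fold, null_mean_spectrum

from conftest import random_shape


def make_model(rng, n=10, theta=0.05, L=500, **kw):
    return MomentModel(n=n, xibar=random_shape(rng, n), theta=theta, L=L, **kw)


class TestPoissonMoments:
    def test_printed_second_moments(self, rng):
        mu = rng.uniform(0.1, 3.0, 6)
        assert np.isclose(poisson_moment(mu, (1, 3)), mu[0] * mu[2])
        assert np.isclose(poisson_moment(mu, (2, 2)), mu[1] + mu[1] ** 2)

    def test_third_moment_against_monte_carlo(self, rng):
        mu = 1.7
        x = rng.poisson(mu, size=1_000_000).astype(float)
        analytic = mu + 3 * mu**2 + mu**3
        se = x.__pow__(3).std() / 1000.0
        assert abs(np.mean(x**3) - analytic) < 3 * se
        assert np.isclose(poisson_moment(np.array([mu]), (1, 1, 1)), analytic)

    def test_zero_theta_kills_all_moments(self):
        mu = np.zeros(5)
        for I in [(1,), (2, 2), (1, 2, 3)]:
            assert poisson_moment(mu, I) == 0.0

    def test_taylor_coefficients_resum_to_the_moment(self, rng):
        shape = random_shape(rng, 7)
        thetaL = 0.8
        for I in [(2,), (3, 3), (1, 2), (2, 2, 5)]:
            coeffs = poisson_moment_taylor(shape, I, len(I))
            resummed = sum(c * thetaL**m for m, c in enumerate(coeffs))
            assert np.isclose(resummed, poisson_moment(thetaL * shape, I), rtol=1e-12)

    def test_multiset_bookkeeping(self):
        assert multiset_multiplicity((1, 1)) == 1
        assert multiset_multiplicity((1, 2)) == 2
        assert multiset_multiplicity((1, 1, 2)) == 3
        ms = multisets_up_to(4, 2)
        assert len(ms) == 4 + 10  # 4 singles + C(5,2) pairs with repetition


class TestFuG:
    def test_expected_quadratic_form_is_the_class_count(self):
        n, theta, L, reps = 12, 0.1, 500, 100_000
        mu = null_mean_spectrum(n, theta, L)
        X = sample_sfs(mu, reps, seed=9)
        Q = np.sum((X - mu) ** 2 / mu, axis=1)
        se = Q.std() / np.sqrt(reps)
        assert abs(Q.mean() - (n - 1)) < 3 * se
        # hence the renormalised statistic is centred
        tg = fu_g_many(X, mu)
        assert abs(tg.mean()) < 3 * tg.std() / np.sqrt(reps)

    def test_exact_null_spectrum_gives_minus_classes_over_sd(self):
        n, theta, L = 10, 0.2, 100
        mu = null_mean_spectrum(n, theta, L)
        spec = SpectrumCounts(n, mu, L=L)
        var = np.sum(1 / mu) + 2 * (n - 1)
        assert np.isclose(fu_g_renormalised(spec, theta_hat=theta),
                          -(n - 1) / np.sqrt(var))
        assert fu_g_diagonal(spec, theta_hat=theta) == 0.0

    def test_renormalisation_is_monotone_hence_power_preserving(self):
        n, theta, L = 10, 0.05, 1000
        mu = null_mean_spectrum(n, theta, L)
        X = sample_sfs(mu, 2000, seed=1)
        Q = np.sum((X - mu) ** 2 / mu, axis=1)
        tg = fu_g_many(X, mu)
        assert np.all(np.diff(tg[np.argsort(Q)]) >= -1e-12)


class TestQuadraticOptimal:
    def test_closed_forms_match_the_general_solver(self, rng):
        for _ in range(5):
            model = make_model(rng, n=int(rng.integers(5, 11)))
            for build, gen in ((quadratic_sc_optimal, "strong"),
                               (quadratic_wc_optimal, "weak")):
                cf = build(model)
                g = general_optimal(model, 2, gen)
                scale = np.max(np.abs(g.coeffs))
                assert np.max(np.abs(cf.coeffs - g.coeffs)) < 1e-6 * scale
                assert np.isclose(cf.gamma, g.gamma, atol=1e-6 * max(scale, 1.0))

    def test_identical_alternative_gives_identically_zero_weights(self, rng):
        n = 8
        model = MomentModel(n=n, xibar=1.0 / np.arange(1, n), theta=0.05, L=100)
        with pytest.raises(ZeroDivisionError):
            quadratic_sc_optimal(model)
        with pytest.raises(ZeroDivisionError):
            quadratic_wc_optimal(model)

    def test_variance_equals_alternative_expectation(self, rng):
        for _ in range(20):
            model = make_model(rng, n=int(rng.integers(5, 12)))
            for t in (quadratic_sc_optimal(model), quadratic_wc_optimal(model)):
                v, e = t.null_variance(), t.alt_expectation()
                assert abs(v / e - 1.0) < 1e-9

    def test_strong_centring_robust_to_theta_plug_in(self, rng):
        """Monte-Carlo null mean of the unnormalised strongly centred
        statistic stays at 0 when the weights are built at theta/2, theta
        and 2 theta; the weakly centred test is centred only at theta."""
        n, theta, L, reps = 10, 0.05, 1000, 100_000
        model = make_model(rng, n=n, theta=theta, L=L)
        mu = model.mu
        X = sample_sfs(mu, reps, seed=13)
        for factor in (0.5, 1.0, 2.0):
            m = model.at_theta(theta * factor)
            sc = quadratic_sc_optimal(m)
            stats = sc.evaluate_many(X)
            assert abs(stats.mean()) < 3 * stats.std() / np.sqrt(reps)
            wc = quadratic_wc_optimal(m)
            wstats = wc.evaluate_many(X)
            departs = abs(wstats.mean()) > 3 * wstats.std() / np.sqrt(reps)
            assert departs == (factor != 1.0)

    def test_normalised_statistics_have_zero_mean_unit_variance(self, rng):
        n, theta, L, reps = 10, 0.05, 1000, 100_000
        model = make_model(rng, n=n, theta=theta, L=L)
        X = sample_sfs(model.mu, reps, seed=17)
        for t in (quadratic_sc_optimal(model), quadratic_wc_optimal(model)):
            stats = t.evaluate_many(X)
            assert abs(stats.mean()) < 3 * stats.std() / np.sqrt(reps)
            assert abs(stats.var() - 1.0) < 0.1


class TestWeaklyCentredLinear:
    def test_weights_and_maximum(self, rng):
        model = make_model(rng)
        t = linear_wc_optimal(model)
        mu, mubar = model.mu, model.mubar
        assert np.allclose(t.coeffs, (mubar - mu) / mu)
        assert np.isclose(t.gamma, -float(mu @ ((mubar - mu) / mu)))
        assert np.isclose(t.alt_expectation(), wc_linear_max_expectation(model))

    def test_weak_maximum_dominates_strong_linear_maximum(self, rng):
        for _ in range(1000):
            n = int(rng.integers(4, 15))
            model = make_model(rng, n=n)
            assert (wc_linear_max_expectation(model)
                    >= sc_linear_max_expectation(model) - 1e-12)

    def test_alternative_mean_matches_monte_carlo(self, rng):
        n, theta, L, reps = 10, 0.05, 800, 100_000
        model = make_model(rng, n=n, theta=theta, L=L)
        t = linear_wc_optimal(model)
        X = sample_sfs(model.mubar, reps, seed=19)
        nums = t.gamma + X @ t.coeffs
        se = nums.std() / np.sqrt(reps)
        assert abs(nums.mean() - wc_linear_max_expectation(model)) < 3 * se


class TestGeneralOptimal:
    def test_degree_one_strong_is_the_linear_optimal_test(self, rng):
        n = 6
        model = make_model(rng, n=n)
        t = general_optimal(model, 1, "strong")
        # implied linear weights: Omega_i = coeff_i * xi0_i (up to scale)
        from sfstests.optimal_linear import ScenarioSpectra, optimal_linear_weights
        scen = ScenarioSpectra(n=n, xibar=model.xibar, theta=model.theta, L=model.L)
        usual = optimal_linear_weights(scen)
        implied = t.coeffs * model.xi0
        ratio = implied[np.abs(usual) > 1e-9] / usual[np.abs(usual) > 1e-9]
        assert np.allclose(ratio, ratio[0], rtol=1e-8)

    def test_degree_monotonicity_of_the_alternative_mean(self, rng):
        """Higher-degree strongly centred optima achieve a larger normalised
        alternative mean (E_norm = sqrt(alt expectation))."""
        for _ in range(50):
            model = make_model(rng, n=int(rng.integers(5, 10)))
            e1 = general_optimal(model, 1, "strong").alt_expectation()
            e2 = general_optimal(model, 2, "strong").alt_expectation()
            assert e2 >= e1 - 1e-9 * abs(e1)

    def test_second_moment_matrices_give_the_same_strong_test(self, rng):
        """Replacing the inverse covariance by the inverse raw second-moment
        matrix leaves the strongly centred optimal test unchanged."""
        model = make_model(rng, n=7)
        ms = multisets_up_to(len(model.xi0), 2)
        C = model.covariance_matrix(ms)
        mu = model.moment_vector(ms)
        mubar = model.moment_vector(ms, alt=True)
        M2 = C + np.outer(mu, mu)
        U = model.taylor_matrix(ms, 2)

        def strong(mat):
            a = _solve_spd(mat, mubar)
            B = _solve_spd(mat, U)
            beta = np.linalg.solve(U.T @ B, U.T @ a)
            return a - B @ beta

        c1, c2 = strong(C), strong(M2)
        X = sample_sfs(model.mu, 5, seed=23)
        t1 = PolynomialTest(2, model.n, ms, c1, 0.0, "strong", model)
        t2 = PolynomialTest(2, model.n, ms, c2, 0.0, "strong", model)
        s1 = t1.evaluate_many(X)
        s2 = t2.evaluate_many(X)
        assert np.allclose(s1, s2, rtol=1e-8)

    def test_multiset_cap_guard(self, rng):
        model = make_model(rng, n=30)
        with pytest.raises(ValueError, match="cap"):
            general_optimal(model, 3, "strong", cap=100)


class TestFoldedVariants:
    def test_quadratic_identities_hold_on_the_folded_spectrum(self, rng):
        n, theta, L = 11, 0.08, 400
        xibar_unf = random_shape(rng, n)
        xibar_f = fold(SpectrumCounts(n, xibar_unf)).counts
        model = MomentModel(n=n, xibar=xibar_f, theta=theta, L=L, folded=True)
        for t in (quadratic_sc_optimal(model), quadratic_wc_optimal(model)):
            assert abs(t.null_variance() / t.alt_expectation() - 1.0) < 1e-9
            assert abs(t.null_expectation()) < 1e-9 * t.null_variance()
        sc = quadratic_sc_optimal(model)
        assert abs(sc.null_expectation(model.at_theta(2 * theta))) < 1e-7


class TestEvaluation:
    def test_vectorised_and_scalar_paths_agree(self, rng):
        model = make_model(rng, n=9)
        t = quadratic_wc_optimal(model)
        X = sample_sfs(model.mu, 20, seed=29)
        many = t.evaluate_many(X)
        one_by_one = [t.evaluate(SpectrumCounts(9, x, L=model.L)) for x in X]
        assert np.allclose(many, one_by_one, rtol=1e-12)

    def test_watterson_policy_plugs_in_the_observed_theta(self, rng):
        model = make_model(rng, n=9, theta_policy="watterson")
        t = quadratic_sc_optimal(model)
        spec = SpectrumCounts(9, sample_sfs(model.mu, 1, seed=31)[0], L=model.L)
        from sfstests.spectrum import watterson_theta
        explicit = t.evaluate(spec, theta_hat=watterson_theta(spec))
        assert np.isclose(evaluate_polynomial(t, spec), explicit, rtol=1e-12)

    def test_degenerate_all_zero_weights_raise(self, rng):
        model = make_model(rng, n=6)
        ms = multisets_up_to(5, 1)
        t = PolynomialTest(1, 6, ms, np.zeros(5), 0.0, "weak", model)
        with pytest.raises(ZeroDivisionError):
            t.evaluate(SpectrumCounts(6, np.ones(5)))

    def test_strong_degree_one_reduces_to_linear_evaluation(self, rng):
        """The mapping Omega_i = W^(1)_i * xi0_i turns a degree-1 strongly
        centred test into an ordinary linear test with the same numerator."""
        model = make_model(rng, n=8)
        t = general_optimal(model, 1, "strong")
        Om = t.coeffs * model.xi0
        assert abs(Om.sum()) < 1e-9 * np.abs(Om).sum()  # order-1 centring
        lin = LinearTest(Om, "reduced")
        X = sample_sfs(model.mu, 10, seed=37)
        for x in X:
            spec = SpectrumCounts(8, x, L=model.L)
            assert np.isclose(lin.numerator(spec), float(t.coeffs @ x), rtol=1e-12)
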