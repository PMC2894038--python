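import numpy as np
import pytest

from vbsa.bench import (
    additive_function,
    product_exponential_function,
    pure_interaction_function,
    quadratic_function,
    tensor_quadrature_oracle,
)
from vbsa.estimators import (
    da_estimate,
    finite_difference_derivatives,
    gauss_hermite_rule,
    ghi_estimate,
    hermite_basis,
    lhs_gaussian,
    mc_estimate,
    oha_estimate,
    pa_estimate,
)


class TestLhsGaussian:
    def test_one_sample_per_stratum(self):
        L, sig = 64, np.array([1.0, 2.0])
        W = lhs_gaussian(L, sig, rng=np.random.default_rng(0))
        from scipy.special import ndtr

        for j in range(2):
            strata = np.floor(ndtr(W[:, j] / sig[j]) * L).astype(int)
            assert sorted(strata) == list(range(L))

    def test_seeded_determinism(self):
        a = lhs_gaussian(50, [1.0], rng=np.random.default_rng(42))
        b = lhs_gaussian(50, [1.0], rng=np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_moments_approach_target(self):
        sig = np.array([0.5, 2.0])
        W = lhs_gaussian(4000, sig, rng=np.random.default_rng(1))
        np.testing.assert_allclose(W.mean(axis=0), 0.0,
                                   atol=3 / np.sqrt(4000) * sig.max())
        np.testing.assert_allclose(W.std(axis=0), sig, rtol=0.05)


class TestFiniteDifferences:
    def test_quadratic_axis_exact(self):
        sur = finite_difference_derivatives(lambda w: w[0] ** 2, np.ones(1))
        assert sur.grad[0] == pytest.approx(0.0, abs=1e-12)
        assert sur.hess[0, 0] == pytest.approx(2.0, rel=1e-10)

    def test_bilinear_cross_exact(self):
        sur = finite_difference_derivatives(lambda w: w[0] * w[1], np.ones(2))
        assert sur.hess[0, 1] == pytest.approx(1.0, rel=1e-10)
        np.testing.assert_allclose(sur.grad, 0.0, atol=1e-12)

    def test_quartic_exactness_of_five_point_stencil(self):
        # d2/dw2 w^4 = 12 w^2 -> 0 at the origin; the 5-point stencil is
        # degree-4 exact, a 3-point stencil would report 2*delta^2
        sur = finite_difference_derivatives(lambda w: w[0] ** 4, np.ones(1),
                                            delta=0.1)
        assert abs(sur.hess[0, 0]) < 1e-9
        three_point = ((0.1 ** 4) - 0 + (0.1 ** 4)) / 0.1 ** 2
        assert three_point == pytest.approx(2 * 0.1 ** 2)


class TestDerivativeApproximation:
    def test_linear_plus_quadratic_closed_form(self):
        fn = quadratic_function([1.0, 0.0], [0.0, 1.0], None, np.ones(2))
        dec = da_estimate(fn, fn.sigmas)
        np.testing.assert_allclose(dec.Vj, [1.0, 2.0], rtol=1e-9)
        assert dec.Vjj[0, 1] == pytest.approx(0.0, abs=1e-9)
        from vbsa.variance import sesi_jesi

        rep = sesi_jesi(dec)
        np.testing.assert_allclose(rep.sesi, [1 / 3, 2 / 3], rtol=1e-9)

    def test_additive_has_zero_jesi(self):
        fn = additive_function(np.full(3, 0.5))
        dec = da_estimate(fn, fn.sigmas)
        np.testing.assert_allclose(dec.Vjj, 0.0, atol=1e-10)

    def test_cubic_interaction_blind_spot(self):
        """DA cannot see the w1*w2^2 interaction (third derivative); the
        tensor oracle confirms it is real."""
        def f(W):
            W = np.atleast_2d(W)
            return W[:, 0] * W[:, 1] ** 2

        class Fn:
            sigmas = np.ones(2)
            batch = staticmethod(f)

            def __call__(self, w):
                return float(f(w)[0])

        fn = Fn()
        dec = da_estimate(fn, fn.sigmas)
        oracle = tensor_quadrature_oracle(fn, fn.sigmas, Q=10)
        assert oracle.Vjj[0, 1] > 1.0          # true interaction is large
        assert dec.Vjj[0, 1] < 1e-9            # DA reports none


class TestPolynomialApproximation:
    def test_exact_recovery_with_cross_term(self):
        # f = 1 + 2 w1 + 3 w1^2 + 4 w1 w2: V1 = 4 + 18 = 22, V12 = 16
        B = np.array([[0.0, 4.0], [4.0, 0.0]])
        fn = quadratic_function([2.0, 0.0], [3.0, 0.0], B, np.ones(2))
        dec = pa_estimate(fn, fn.sigmas, S=4)
        assert dec.Vj[0] == pytest.approx(22.0, rel=1e-10)
        assert dec.Vjj[0, 1] == pytest.approx(16.0, rel=1e-10)
        assert dec.meta["surrogate"].alpha0 == pytest.approx(0.0, abs=1e-12)

    def test_additive_quadratic_zero_pairs(self):
        fn = quadratic_function([1.0, -2.0, 0.5], [0.3, 0.1, -0.4], None,
                                np.full(3, 0.7))
        dec = pa_estimate(fn, fn.sigmas, S=4)
        np.testing.assert_allclose(dec.Vjj, 0.0, atol=1e-12)
        np.testing.assert_allclose(dec.Vj, fn.Vj, rtol=1e-10)

    def test_odd_s_rejected(self):
        fn = additive_function(np.ones(2))
        with pytest.raises(ValueError):
            pa_estimate(fn, fn.sigmas, S=3)


class TestGaussHermite:
    def test_two_point_rule(self):
        rule = gauss_hermite_rule(2)
        np.testing.assert_allclose(sorted(rule.nodes), [-1.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(rule.weights, [0.5, 0.5])

    def test_order_five_nodes(self):
        rule = gauss_hermite_rule(5)
        np.testing.assert_allclose(
            sorted(np.abs(rule.nodes)),
            [0.0, 1.35563, 1.35563, 2.85697, 2.85697], atol=1e-5)

    def test_polynomial_exactness_to_degree_2q_minus_1(self):
        from math import prod

        rule = gauss_hermite_rule(5)
        for k in range(10):
            moment = (rule.weights * rule.nodes ** k).sum()
            expected = 0.0 if k % 2 else prod(range(1, k, 2))  # (k-1)!!
            assert moment == pytest.approx(expected, abs=1e-9)

    def test_weights_normalized_and_nodes_symmetric(self):
        for Q in (3, 8, 15):
            rule = gauss_hermite_rule(Q)
            assert rule.weights.sum() == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(sorted(rule.nodes),
                                       sorted(-rule.nodes), atol=1e-10)


class TestGhi:
    def test_exact_on_per_factor_degree_two(self):
        rng = np.random.default_rng(5)
        sig = rng.uniform(0.2, 0.8, 4)
        B = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        B[iu] = rng.normal(size=6)
        B += B.T
        fn = quadratic_function(rng.normal(size=4), rng.normal(size=4), B, sig)
        dec = ghi_estimate(fn, fn.sigmas, Q=5)
        np.testing.assert_allclose(dec.Vj, fn.Vj, rtol=1e-10)
        np.testing.assert_allclose(dec.Vjj, fn.Vjj, rtol=1e-10, atol=1e-12)

    def test_constant_function_all_zero(self):
        class Const:
            def __call__(self, w):
                return 3.14

        dec = ghi_estimate(Const(), np.ones(3), Q=5)
        np.testing.assert_allclose(dec.Vj, 0.0, atol=1e-20)
        np.testing.assert_allclose(dec.Vjj, 0.0, atol=1e-20)

    def test_product_exponential_convergence_in_q(self):
        fn = product_exponential_function([0.5, 0.5], [1.0, 1.0])
        errs = []
        for Q in (3, 5, 9):
            dec = ghi_estimate(fn, fn.sigmas, Q=Q)
            errs.append(abs(dec.Vjj[0, 1] - fn.Vjj[0, 1]) / fn.Vjj[0, 1])
        assert errs[1] < errs[0] and errs[2] < 1e-6

    def test_matches_tensor_oracle_on_smooth_nonpolynomial(self):
        """For J=2 the cut-HDMR truncation is exact, so high-Q GHI must
        reproduce the full ANOVA of a smooth function."""
        def f(W):
            W = np.atleast_2d(W)
            return np.sin(W[:, 0] + 0.5 * W[:, 1]) + 0.3 * np.cos(W[:, 1])

        class Fn:
            sigmas = np.array([0.6, 0.6])
            batch = staticmethod(f)

            def __call__(self, w):
                return float(f(w)[0])

        fn = Fn()
        oracle = tensor_quadrature_oracle(fn, fn.sigmas, Q=30)
        dec = ghi_estimate(fn, fn.sigmas, Q=20)
        np.testing.assert_allclose(dec.Vj, oracle.Vj, rtol=1e-8, atol=1e-12)
        np.testing.assert_allclose(dec.Vjj, oracle.Vjj, rtol=1e-6, atol=1e-12)


class TestHermiteBasis:
    def test_values(self):
        assert hermite_basis(2, 1.0) == pytest.approx(0.0)
        assert hermite_basis(2, 0.0) == pytest.approx(-1 / np.sqrt(2))
        assert hermite_basis(1, 0.7) == 0.7
        assert hermite_basis(0, 5.0) == 1.0

    def test_orthonormality_under_standard_normal(self):
        rule = gauss_hermite_rule(20)
        for k in range(3):
            for l in range(3):
                inner = (rule.weights * hermite_basis(k, rule.nodes)
                         * hermite_basis(l, rule.nodes)).sum()
                assert inner == pytest.approx(float(k == l), abs=1e-10)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            hermite_basis(3, 0.0)


class TestOha:
    def test_recovery_of_in_span_function(self):
        # f = w + (w^2 - 1) = psi1 + sqrt(2) psi2 at unit sigma: V1 = 3
        def f(W):
            W = np.atleast_2d(W)
            return W[:, 0] + W[:, 0] ** 2 - 1.0

        class Fn:
            sigmas = np.ones(2)
            batch = staticmethod(f)

            def __call__(self, w):
                return float(f(w)[0])

        dec = oha_estimate(Fn(), np.ones(2), L=200, seed=3)
        assert dec.Vj[0] == pytest.approx(3.0, rel=1e-8)
        assert dec.Vj[1] == pytest.approx(0.0, abs=1e-10)
        sur = dec.meta["surrogate"]
        assert sur.axis[0, 0] == pytest.approx(1.0, rel=1e-8)
        assert sur.axis[0, 1] == pytest.approx(np.sqrt(2.0), rel=1e-8)

    def test_exact_on_quadratic_with_interactions(self):
        rng = np.random.default_rng(11)
        sig = rng.uniform(0.3, 1.0, 3)
        B = np.zeros((3, 3))
        iu = np.triu_indices(3, 1)
        B[iu] = rng.normal(size=3)
        B += B.T
        fn = quadratic_function(rng.normal(size=3), rng.normal(size=3), B, sig)
        dec = oha_estimate(fn, fn.sigmas, L=500, seed=0)
        np.testing.assert_allclose(dec.Vj, fn.Vj, rtol=1e-8)
        np.testing.assert_allclose(dec.Vjj, fn.Vjj, rtol=1e-8, atol=1e-10)

    def test_insufficient_samples_rejected(self):
        fn = additive_function(np.ones(3))
        with pytest.raises(ValueError):
            oha_estimate(fn, fn.sigmas, L=10)

    def test_seeded_determinism(self):
        fn = product_exponential_function([0.3, 0.3], [1.0, 1.0])
        a = oha_estimate(fn, fn.sigmas, L=500, seed=9)
        b = oha_estimate(fn, fn.sigmas, L=500, seed=9)
        np.testing.assert_array_equal(a.Vj, b.Vj)
        np.testing.assert_array_equal(a.Vjj, b.Vjj)


class TestMonteCarlo:
    def test_additive_first_order_recovery(self):
        fn = additive_function(np.ones(3))
        dec = mc_estimate(fn, fn.sigmas, L=4000, seed=2)
        np.testing.assert_allclose(dec.Vj, 1.0, atol=5 / np.sqrt(4000))
        # the closed-pair estimator subtracts two first-order estimates, so
        # its noise constant is larger than the first-order one
        assert np.abs(dec.meta["raw_Vjj"]).max() < 10 / np.sqrt(4000)

    def test_pure_interaction_recovery(self):
        fn = pure_interaction_function(np.ones(2))
        dec = mc_estimate(fn, fn.sigmas, L=8000, seed=4)
        assert dec.Vjj[0, 1] == pytest.approx(1.0, abs=5 / np.sqrt(8000))
        np.testing.assert_allclose(dec.meta["raw_Vj"], 0.0,
                                   atol=5 / np.sqrt(8000))

    def test_constant_function_exactly_zero_after_clamp(self):
        class Const:
            def __call__(self, w):
                return 7.0

        dec = mc_estimate(Const(), np.ones(2), L=200, seed=0)
        np.testing.assert_array_equal(dec.Vj, 0.0)
        np.testing.assert_array_equal(dec.Vjj, 0.0)

    def test_vtot_estimate_recorded(self):
        fn = additive_function(np.ones(2))
        dec = mc_estimate(fn, fn.sigmas, L=2000, seed=1)
        assert dec.meta["Vtot_estimate"] == pytest.approx(2.0, rel=0.1)


class TestCrossMethodProperties:
    def test_all_methods_zero_jesi_on_additive(self):
        fn = quadratic_function([1.0, -1.0, 0.5], [0.4, 0.2, -0.3], None,
                                np.full(3, 0.5))
        noise_floor = {
            "da": 1e-10, "pa": 1e-10, "ghi": 1e-10, "oha": 1e-8, "mc": 0.15,
        }
        decs = {
            "da": da_estimate(fn, fn.sigmas),
            "pa": pa_estimate(fn, fn.sigmas),
            "ghi": ghi_estimate(fn, fn.sigmas),
            "oha": oha_estimate(fn, fn.sigmas, L=500, seed=0),
            "mc": mc_estimate(fn, fn.sigmas, L=2000, seed=0),
        }
        for name, dec in decs.items():
            assert np.abs(dec.meta["raw_Vjj"]).max() < noise_floor[name], name
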