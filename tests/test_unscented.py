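"""Scaled unscented transform: sigma points, weights, propagation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from totalnoise import (
    ParameterDistribution,
    UTConfig,
    lognormal_sigma_points,
    sigma_points,
    ut_propagate,
)


def _random_psd(rng, L, scale=1.0):
    A = rng.normal(size=(L, L))
    return scale * (A @ A.T) / L


class TestSigmaPoints:
    def test_hand_evaluated_scalar_case(self):
        """L=1, mean 5, var 4, alpha=1, beta=2, kappa=2 -> lambda=2:
        points {5, 5+2*sqrt(3), 5-2*sqrt(3)}, mean weights (2/3, 1/6, 1/6)."""
        d = ParameterDistribution(("k",), [5.0], [[4.0]])
        sp = sigma_points(d, UTConfig(alpha=1, beta=2, kappa=2))
        r = 2 * math.sqrt(3)
        np.testing.assert_allclose(sp.points.ravel(), [5.0, 5.0 + r, 5.0 - r])
        np.testing.assert_allclose(sp.mean_weights, [2 / 3, 1 / 6, 1 / 6])
        np.testing.assert_allclose(sp.cov_weights[0], 2 / 3 + 2.0)

    def test_count_and_weight_normalization(self, rng):
        for L in range(1, 9):
            d = ParameterDistribution(
                tuple(f"p{i}" for i in range(L)),
                rng.uniform(1, 10, L),
                _random_psd(rng, L),
            )
            sp = sigma_points(d)
            assert len(sp) == 2 * L + 1
            assert sp.mean_weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_input_moment_recovery(self, rng):
        """Weighted points reproduce the input mean and covariance exactly."""
        for L in range(1, 9):
            mean = rng.uniform(0.5, 20, L)
            cov = _random_psd(rng, L)
            d = ParameterDistribution(tuple(f"p{i}" for i in range(L)), mean, cov)
            sp = sigma_points(d)
            np.testing.assert_allclose(
                sp.mean_weights @ sp.points, mean, rtol=1e-10, atol=1e-10
            )
            D = sp.points - mean
            np.testing.assert_allclose(
                (sp.cov_weights * D.T) @ D, cov, rtol=1e-9, atol=1e-10
            )

    def test_zero_covariance_degenerates_to_mean(self):
        d = ParameterDistribution(("a", "b"), [3.0, 4.0], np.zeros((2, 2)))
        sp = sigma_points(d)
        assert np.all(sp.points == [3.0, 4.0])

    def test_invalid_config_rejected(self):
        d = ParameterDistribution(("a",), [1.0], [[1.0]])
        with pytest.raises(ValueError, match="lambda"):
            sigma_points(d, UTConfig(alpha=0.1, beta=2, kappa=-1))

    def test_negative_coordinate_warns(self):
        d = ParameterDistribution(("k",), [1.0], [[100.0]])
        with pytest.warns(UserWarning, match="lognormal"):
            sigma_points(d)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_permutation_equivariance(self, seed):
        """Permuting the parameter order permutes sigma-point coordinates and
        leaves the propagated output moments unchanged."""
        rng = np.random.default_rng(seed)
        L = 3
        mean = rng.uniform(1, 5, L)
        cov = _random_psd(rng, L)
        perm = rng.permutation(L)
        d1 = ParameterDistribution(("a", "b", "c"), mean, cov)
        d2 = ParameterDistribution(
            tuple(np.array(["a", "b", "c"])[perm]),
            mean[perm],
            cov[np.ix_(perm, perm)],
        )
        w = rng.uniform(0.5, 2.0, L)

        def g1(x):
            return [w @ x, (w * x) @ x]

        def g2(x):
            return [w[perm] @ x, (w[perm] * x) @ x]

        m1, c1 = ut_propagate(sigma_points(d1), g1)
        m2, c2 = ut_propagate(sigma_points(d2), g2)
        np.testing.assert_allclose(m1, m2, rtol=1e-9)
        np.testing.assert_allclose(c1, c2, rtol=1e-8, atol=1e-10)


class TestPropagation:
    def test_linear_map_exact(self):
        d = ParameterDistribution(("k",), [2.0], [[4.0]])
        mu, cov = ut_propagate(sigma_points(d), lambda th: 3 * th + 1)
        assert mu[0] == pytest.approx(7.0, abs=1e-12)
        assert cov[0, 0] == pytest.approx(36.0, abs=1e-10)

    def test_quadratic_mean_matches_second_moment(self):
        """g(x)=x^2 with x~N(0,1): UT mean equals E[x^2]=1 by hand evaluation
        of the three points at alpha=1, beta=2, kappa=2."""
        d = ParameterDistribution(("x",), [0.0], [[1.0]])
        sp = sigma_points(d, UTConfig(alpha=1, beta=2, kappa=2))
        mu, _ = ut_propagate(sp, lambda th: th**2)
        assert mu[0] == pytest.approx(1.0, abs=1e-12)

    def test_identity_recovers_input(self, rng):
        L = 4
        mean = rng.uniform(1, 5, L)
        cov = _random_psd(rng, L)
        d = ParameterDistribution(tuple("abcd"), mean, cov)
        mu, c = ut_propagate(sigma_points(d), lambda th: th)
        np.testing.assert_allclose(mu, mean, rtol=1e-10)
        np.testing.assert_allclose(c, cov, rtol=1e-9, atol=1e-12)

    def test_mapping_failure_reports_point_index(self):
        d = ParameterDistribution(("k",), [1.0], [[0.04]])

        def bad(th):
            if th[0] > 1.0:
                raise FloatingPointError("boom")
            return th

        with pytest.raises(RuntimeError, match="sigma point 1"):
            ut_propagate(sigma_points(d), bad)

    def test_matches_monte_carlo_for_smooth_map(self, rng):
        """UT mean within 3 MC standard errors for a nonlinear map at CV 0.2."""
        d = ParameterDistribution(("k",), [2.0], [[(0.2 * 2.0) ** 2]])
        g = lambda th: np.atleast_1d(np.exp(0.5 * th[0]) + th[0] ** 2)
        mu, _ = ut_propagate(sigma_points(d), g)
        draws = rng.normal(2.0, 0.4, size=100_000)
        vals = np.exp(0.5 * draws) + draws**2
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(mu[0] - vals.mean()) < 3 * se

    def test_cost_is_2L_plus_1_evaluations(self):
        d = ParameterDistribution(tuple("abcde"), np.ones(5), np.eye(5) * 0.01)
        calls = []
        ut_propagate(sigma_points(d), lambda th: (calls.append(1), th)[1])
        assert len(calls) == 2 * 5 + 1


class TestLognormal:
    def test_requires_lognormal_scale_and_positive_mean(self):
        d = ParameterDistribution(("k",), [1.0], [[0.01]])
        with pytest.raises(ValueError):
            lognormal_sigma_points(d)
        with pytest.raises(ValueError, match="positive"):
            lognormal_sigma_points(
                ParameterDistribution(("k",), [-1.0], [[0.01]], scale="lognormal")
            )

    def test_zero_covariance_all_points_at_mean(self):
        d = ParameterDistribution(("k",), [3.0], [[0.0]], scale="lognormal")
        sp = lognormal_sigma_points(d)
        np.testing.assert_allclose(sp.points, 3.0)

    def test_points_strictly_positive(self, rng):
        for _ in range(10):
            L = 3
            mean = rng.uniform(0.1, 10, L)
            cov = _random_psd(rng, L, scale=5.0)
            d = ParameterDistribution(
                tuple(f"p{i}" for i in range(L)), mean, cov, scale="lognormal"
            )
            assert np.all(lognormal_sigma_points(d).points > 0)

    def test_weighted_mean_recovers_lognormal_mean(self):
        """For log-space sd s <= 0.2 the exponentiated points reproduce the
        log-normal mean exp(m + s^2/2) to within 1% (UT is second order)."""
        for s in (0.05, 0.1, 0.2):
            m = 0.7
            natural_mean = math.exp(m + s**2 / 2)
            natural_var = (math.exp(s**2) - 1) * natural_mean**2
            d = ParameterDistribution(
                ("k",), [natural_mean], [[natural_var]], scale="lognormal"
            )
            sp = lognormal_sigma_points(d)
            got = sp.mean_weights @ sp.points
            assert got[0] == pytest.approx(natural_mean, rel=0.01)
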