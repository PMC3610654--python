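"""Total-variability decomposition, CV^2 measures, ellipse geometry."""

import math

import numpy as np
import pytest
from scipy import stats

from totalnoise import (
    ParameterDistribution,
    circuit_post_transcriptional,
    circuit_single_gene,
    circuit_transcriptional_autoreg,
    cv2,
    ellipse_contour,
    mixture_sample,
    relative_cv2,
    steady_state_lna,
    total_moments,
)


class TestTotalMoments:
    def test_zero_covariance_equals_fixed_theta(self, single_gene):
        dist = ParameterDistribution(("k_R",), [1.0], [[0.0]])
        res = total_moments(single_gene, dist)
        ss = steady_state_lna(single_gene)
        np.testing.assert_allclose(res.total_mean, ss.mean, rtol=1e-9)
        np.testing.assert_allclose(res.total_cov, ss.cov, rtol=1e-9)
        assert np.all(res.extrinsic_cov == 0)

    def test_decomposition_sums_exactly(self, single_gene):
        dist = ParameterDistribution.from_cv(("k_R", "k_P"), [1.0, 1.0], 0.1)
        res = total_moments(single_gene, dist)
        np.testing.assert_array_equal(
            res.total_cov, res.intrinsic_cov + res.extrinsic_cov
        )
        for C in (res.intrinsic_cov, res.extrinsic_cov):
            np.testing.assert_allclose(C, C.T, atol=1e-10)
            assert np.linalg.eigvalsh(C).min() >= -1e-8 * max(np.trace(C), 1.0)

    def test_irrelevant_parameter_contributes_nothing(self):
        """Varying gamma_M with k_b = 0 cannot move the protein: its extrinsic
        row/column vanishes (constant map)."""
        net = circuit_post_transcriptional(theta={"k_b": 0.0})
        dist = ParameterDistribution(("gamma_M",), [0.1], [[1e-4]])
        res = total_moments(net, dist)
        i = net.species_index("P")
        np.testing.assert_allclose(res.extrinsic_cov[i, :], 0.0, atol=1e-8)
        np.testing.assert_allclose(res.extrinsic_cov[:, i], 0.0, atol=1e-8)

    def test_linear_parameter_exact_decomposition(self, single_gene):
        """k_R enters every steady-state moment linearly, so the UT is exact:
        extrinsic Var(P) = (d phi_P / d k_R)^2 sigma^2 = (1e5 * 0.01)^2."""
        a = 0.1
        dist = ParameterDistribution(("k_R",), [1.0], [[a**2]])
        res = total_moments(single_gene, dist)
        slope = 1.0 * 1.0 / (0.1 * 0.01)  # k_P D0/(gamma_R gamma_P)
        assert res.var_of("P", "extrinsic") == pytest.approx(
            (slope * a) ** 2, rel=1e-8
        )
        assert res.mean_of("P") == pytest.approx(1000.0, rel=1e-8)

    def test_extrinsic_grows_with_cv(self, single_gene):
        prev = -1.0
        for a in (0.01, 0.05, 0.1):
            dist = ParameterDistribution.from_cv(("k_R",), [1.0], a)
            res = total_moments(single_gene, dist)
            cur = res.var_of("P", "extrinsic")
            assert cur > prev
            prev = cur

    def test_transient_mode(self, single_gene):
        dist = ParameterDistribution.from_cv(("k_R",), [1.0], 0.1)
        res = total_moments(single_gene, dist, when=50.0)
        assert res.when == 50.0
        assert 0 < res.mean_of("P") < 1000.0

    def test_unstable_sigma_point_reported(self):
        net = circuit_transcriptional_autoreg(n=2, K=100.0)
        dist = ParameterDistribution(("gamma_P",), [0.01], [[0.01]])
        with pytest.raises(RuntimeError, match="sigma point"):
            total_moments(net, dist)


class TestMixtureSample:
    def test_agrees_with_total_moments_within_3se(self, single_gene):
        dist = ParameterDistribution.from_cv(("k_R",), [1.0], 0.1)
        res = total_moments(single_gene, dist)
        n = 4000
        samples = mixture_sample(single_gene, dist, n=n, seed=12)
        i = single_gene.species_index("P")
        se_mean = samples[:, i].std(ddof=1) / math.sqrt(n)
        assert abs(samples[:, i].mean() - res.total_mean[i]) < 3 * se_mean
        v = samples[:, i].var(ddof=1)
        m4 = stats.moment(samples[:, i], 4)
        se_var = math.sqrt(max(m4 - v**2 * (n - 3) / (n - 1), 0.0) / n)
        assert abs(v - res.total_cov[i, i]) < 3 * se_var

    def test_seed_determinism(self, single_gene):
        dist = ParameterDistribution.from_cv(("k_R",), [1.0], 0.05)
        a = mixture_sample(single_gene, dist, n=50, seed=3)
        b = mixture_sample(single_gene, dist, n=50, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_zero_cov_reduces_to_conditional_gaussian(self, single_gene):
        dist = ParameterDistribution(("k_R",), [1.0], [[0.0]])
        s = mixture_sample(single_gene, dist, n=3000, seed=8)
        ss = steady_state_lna(single_gene)
        i = single_gene.species_index("P")
        se = math.sqrt(ss.cov[i, i] / 3000)
        assert abs(s[:, i].mean() - ss.mean[i]) < 3 * se


class TestCv2:
    def test_basic_values(self):
        assert cv2(100.0, 400.0) == pytest.approx(0.04)
        assert cv2(50.0, 50.0) == pytest.approx(1 / 50.0)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            cv2(0.0, 1.0)

    def test_relative_cv2_identity_and_continuity(self):
        net = circuit_transcriptional_autoreg(n=2, K=100.0)
        ref = total_moments(net, theta={"s_fb": 0.0})
        assert relative_cv2(ref, ref, "P") == pytest.approx(1.0)
        near = total_moments(net, theta={"s_fb": 1e-10})
        assert relative_cv2(near, ref, "P") == pytest.approx(1.0, abs=1e-6)

    def test_interior_minimum_below_one_for_n2(self):
        """Intrinsic-only sweep at n=2 dips below the no-feedback baseline."""
        net = circuit_transcriptional_autoreg(n=2, K=100.0)
        ref = total_moments(net, theta={"s_fb": 0.0})
        vals = [
            relative_cv2(total_moments(net, theta={"s_fb": s}), ref, "P")
            for s in np.logspace(-4, -2, 7)
        ]
        assert min(vals) < 1.0


class TestEllipse:
    def test_identity_unit_circle(self):
        ell = ellipse_contour([0.0, 0.0], np.eye(2), r=1.0)
        np.testing.assert_allclose(ell.half_lengths, [1.0, 1.0])
        assert ell.contains([[0.5, 0.5]])[0]
        assert not ell.contains([[1.1, 0.0]])[0]

    def test_confidence_half_lengths_from_chi2(self):
        q = stats.chi2.ppf(0.95, 2)
        ell = ellipse_contour([0.0, 0.0], np.diag([4.0, 1.0]), confidence=0.95)
        np.testing.assert_allclose(
            sorted(ell.half_lengths), sorted([math.sqrt(q * 4), math.sqrt(q)])
        )

    def test_rank_deficient_covariance(self):
        ell = ellipse_contour([0.0, 0.0], np.diag([4.0, 0.0]), r=2.0)
        assert min(ell.half_lengths) == 0.0
        assert ell.contains([[0.0, 0.0]])[0]
        assert not ell.contains([[0.0, 0.1]])[0]

    def test_coverage_of_95_percent_contour(self, rng):
        """Fraction of bivariate-normal samples inside the 0.95 ellipse is
        0.95 +/- 0.005 (50,000 samples; correlated covariance)."""
        cov = np.array([[4.0, 1.5], [1.5, 2.0]])
        mean = np.array([3.0, -1.0])
        pts = rng.multivariate_normal(mean, cov, size=50_000)
        ell = ellipse_contour(mean, cov, confidence=0.95)
        frac = ell.contains(pts).mean()
        assert frac == pytest.approx(0.95, abs=0.005)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ellipse_contour([0.0], np.eye(2))
        with pytest.raises(ValueError):
            ellipse_contour([0.0, 0.0], np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ValueError):
            ellipse_contour([0.0, 0.0], np.eye(2), r=1.0, confidence=0.5)
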