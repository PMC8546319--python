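import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pcssreg import (
    ConditionerStats,
    FactorStats,
    Gaussian,
    GenotypeHwe,
    PcssError,
    conditional_covariance,
    conditional_mean,
    conditional_moments,
    conditional_product_mean,
    conditional_product_variance,
    conditional_variance,
    cov_predictor_product,
    pair_product_moments,
    partial_correlation,
    product_mean,
    product_variance,
    unconditional_product_variance,
)


def _stats(v):
    v = np.asarray(v, dtype=float)
    return v.mean(), v.var(ddof=1)


class TestConditionalMean:
    def test_toy_vectors(self):
        # x=(0,1,2,1), y=(1,2,3,2): simple regression gives a=1, b=1
        cm = conditional_mean(2.0, 1.0, 2.0 / 3.0, 2.0 / 3.0)
        assert cm.a == pytest.approx(1.0)
        assert cm.b == pytest.approx(1.0)
        assert cm.mean_at(2.0) == pytest.approx(3.0)

    def test_zero_covariance_constant(self):
        cm = conditional_mean(1.7, 0.0, 1.0, 0.0)
        assert cm.mean_at(-5.0) == cm.mean_at(5.0) == pytest.approx(1.7)

    def test_binary_clamp(self):
        cm = conditional_mean(0.6, 0.0, 1.0, 0.3, binary=True, eps=1e-6)
        # a + b x = 0.6 + 0.3*2 = 1.2 -> clamps to 1 - eps
        assert cm.mean_at(2.0) == pytest.approx(1.0 - 1e-6)
        assert cm.mean_at(-3.0) == pytest.approx(1e-6)

    def test_zero_variance_predictor_degenerate(self):
        cm = conditional_mean(1.0, 3.0, 0.0, 0.5)
        assert cm.b == 0.0 and cm.a == 1.0


class TestConditionalVariance:
    def test_perfect_fit_is_zero(self):
        # toy above: s_y^2 = 2/3, b = 1, s_xy = 2/3, n = 4
        assert conditional_variance(2.0 / 3.0, 2.0 / 3.0, 2.0 / 3.0, 4) == pytest.approx(0.0)

    def test_independent_case(self):
        assert conditional_variance(2.5, 0.0, 1.0, 101) == pytest.approx(100.0 / 99.0 * 2.5)

    def test_binary_variance_at_half(self):
        cm = conditional_mean(0.5, 0.0, 1.0, 0.0, binary=True)
        assert cm.var_at(0.0) == pytest.approx(0.25)

    def test_small_n_rejected(self):
        with pytest.raises(PcssError):
            conditional_variance(1.0, 0.0, 1.0, 2)


class TestPartialCorrelation:
    def test_no_adjustment(self):
        assert partial_correlation(0.5, 0.0, 0.0) == pytest.approx(0.5)

    def test_direct_evaluation(self):
        assert partial_correlation(0.5, 0.6, 0.5) == pytest.approx(0.28867513459481287)

    def test_perfect_marginal_correlation_returns_zero(self):
        assert partial_correlation(0.5, 1.0, 0.3) == 0.0
        assert partial_correlation(0.5, 0.3, -1.0) == 0.0

    def test_matches_residual_correlation_oracle(self, rng):
        # brute force: correlation of OLS residuals on a 3-variable Gaussian sample
        n = 200_000
        L = np.linalg.cholesky(np.array([[1, 0.5, 0.6], [0.5, 1, 0.5], [0.6, 0.5, 1.0]]))
        z = rng.standard_normal((n, 3)) @ L.T
        y1, y2, x = z[:, 0], z[:, 1], z[:, 2]
        r12 = np.corrcoef(y1, y2)[0, 1]
        rx1 = np.corrcoef(x, y1)[0, 1]
        rx2 = np.corrcoef(x, y2)[0, 1]
        e1 = y1 - np.polyval(np.polyfit(x, y1, 1), x)
        e2 = y2 - np.polyval(np.polyfit(x, y2, 1), x)
        oracle = np.corrcoef(e1, e2)[0, 1]
        assert partial_correlation(r12, rx1, rx2) == pytest.approx(oracle, abs=1e-6)

    def test_out_of_range_rejected(self):
        with pytest.raises(PcssError):
            partial_correlation(1.2, 0.0, 0.0)


class TestConditionalCovarianceAndProductMean:
    def test_zero_partial_correlation(self):
        cm = conditional_mean(0.0, 0.0, 1.0, 0.5)
        cm.hvar = 2.0
        for x in (-1.0, 0.0, 3.0):
            assert conditional_covariance(cm, cm, 0.0, x) == 0.0

    def test_unit_variances(self):
        cm = conditional_mean(0.0, 0.0, 1.0, 0.0)
        cm.hvar = 1.0
        assert conditional_covariance(cm, cm, 0.3, 0.0) == pytest.approx(0.3)

    def test_product_mean_formula(self):
        cm1 = conditional_mean(2.0, 0.0, 1.0, 0.0)
        cm2 = conditional_mean(3.0, 0.0, 1.0, 0.0)
        assert conditional_product_mean(cm1, cm2, 0.5, 0.0) == pytest.approx(6.5)
        assert conditional_product_mean(cm1, cm2, 0.0, 0.0) == pytest.approx(6.0)


class TestConditionalProductVariance:
    def test_degenerate_phenotypes(self):
        assert conditional_product_variance(1.0, 2.0, 0.0, 0.0, 0.0) == 0.0

    def test_central_independent(self):
        assert conditional_product_variance(0.0, 0.0, 2.0, 3.0, 0.0) == pytest.approx(6.0)

    def test_against_normal_simulation(self, rng):
        g1, g2, h1, h2, r = 1.2, -0.4, 0.8, 1.5, 0.35
        h12 = r * np.sqrt(h1 * h2)
        n = 2_000_000
        L = np.linalg.cholesky(np.array([[h1, h12], [h12, h2]]))
        z = rng.standard_normal((n, 2)) @ L.T + np.array([g1, g2])
        oracle = np.var(z[:, 0] * z[:, 1], ddof=1)
        est = conditional_product_variance(g1, g2, h1, h2, h12)
        assert est == pytest.approx(oracle, rel=5e-3)

    def test_printed_mode_differs(self):
        normal = conditional_product_variance(2.0, 3.0, 1.0, 1.0, 0.0, mode="normal")
        printed = conditional_product_variance(2.0, 3.0, 1.0, 1.0, 0.0, mode="printed")
        assert normal != printed
        assert normal == pytest.approx(4.0 + 9.0 + 1.0)
        assert printed == pytest.approx(1.0 + 2.0 + 3.0)


class TestCovPredictorProduct:
    def test_constant_conditional_mean(self):
        assert cov_predictor_product(lambda x: np.full_like(x, 5.0), GenotypeHwe(0.3), 0.6) == pytest.approx(0.0)

    def test_identity_conditional_mean(self):
        # genotype MAF 0.5: sum f(x)(x-1) x = 2 p q = 0.5
        assert cov_predictor_product(lambda x: x, GenotypeHwe(0.5), 1.0) == pytest.approx(0.5)

    def test_gaussian_predictor_linear_mean(self):
        # E[(X - mu) (a + b X)] = b sigma^2
        got = cov_predictor_product(lambda x: 2.0 + 3.0 * x, Gaussian(1.0, 2.0), 1.0)
        assert got == pytest.approx(12.0, rel=1e-10)

    def test_missing_distribution(self):
        with pytest.raises(PcssError):
            cov_predictor_product(lambda x: x, None, 0.0)


class TestProductMean:
    def test_zero_covariance(self):
        assert product_mean(2.0, 3.0, 0.0, 50) == pytest.approx(6.0)

    def test_toy_vectors(self):
        # y1=(1,2,3), y2=(2,2,4): mean of products (2,4,12) is 6
        assert product_mean(2.0, 8.0 / 3.0, 1.0, 3) == pytest.approx(6.0)

    @settings(max_examples=60, deadline=None)
    @given(
        arrays(np.float64, st.integers(3, 40), elements=st.floats(-50, 50)),
        st.integers(0, 2**31 - 1),
    )
    def test_exact_identity_property(self, y1, seed):
        rng = np.random.default_rng(seed)
        y2 = rng.uniform(-50, 50, y1.shape[0])
        n = y1.shape[0]
        s12 = np.cov(y1, y2, ddof=1)[0, 1]
        got = product_mean(y1.mean(), y2.mean(), s12, n)
        assert got == pytest.approx(np.mean(y1 * y2), rel=1e-10, abs=1e-10)


def _mc_pair(rng, maf=0.3, b1=0.3, b2=0.2, mu=(1.0, 2.0), sd=(1.0, 0.8), rho=0.4, size=400_000):
    g = rng.binomial(2, maf, size).astype(float)
    L = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
    e = rng.standard_normal((size, 2)) @ L.T
    y1 = mu[0] + b1 * g + sd[0] * e[:, 0]
    y2 = mu[1] + b2 * g + sd[1] * e[:, 1]
    return g, y1, y2


class TestPairProductMoments:
    def _inputs(self, g, y1, y2, maf):
        n = g.shape[0]
        f1 = FactorStats(*_stats(y1))
        f2 = FactorStats(*_stats(y2))
        s12 = np.cov(y1, y2, ddof=1)[0, 1]
        cond = ConditionerStats(
            "g",
            g.mean(),
            g.var(ddof=1),
            GenotypeHwe(g.mean() / 2),
            np.cov(g, y1, ddof=1)[0, 1],
            np.cov(g, y2, ddof=1)[0, 1],
        )
        return n, f1, f2, s12, cond

    def test_matches_simulation_oracle(self, rng):
        g, y1, y2 = _mc_pair(rng)
        n, f1, f2, s12, cond = self._inputs(g, y1, y2, 0.3)
        w_mean, w_var, covs = pair_product_moments(n, f1, f2, s12, [cond])
        w = y1 * y2
        assert w_mean == pytest.approx(w.mean(), rel=1e-10)
        assert w_var == pytest.approx(w.var(ddof=1), rel=0.02)
        assert covs["g"] == pytest.approx(np.cov(g, w, ddof=1)[0, 1], rel=0.05)

    def test_symmetry_under_factor_swap(self, rng):
        g, y1, y2 = _mc_pair(rng, size=5000)
        n, f1, f2, s12, cond = self._inputs(g, y1, y2, 0.3)
        fwd = pair_product_moments(n, f1, f2, s12, [cond])
        swapped_cond = ConditionerStats(
            cond.name, cond.mean, cond.var, cond.dist, cond.cov2, cond.cov1
        )
        rev = pair_product_moments(n, f2, f1, s12, [swapped_cond])
        assert fwd[0] == pytest.approx(rev[0], rel=1e-12)
        assert fwd[1] == pytest.approx(rev[1], rel=1e-12)
        assert fwd[2]["g"] == pytest.approx(rev[2]["g"], rel=1e-12)

    def test_null_predictor_covariance_near_zero(self, rng):
        g, y1, y2 = _mc_pair(rng, b1=0.0, b2=0.0, size=1_000_000)
        n, f1, f2, s12, cond = self._inputs(g, y1, y2, 0.3)
        _, _, covs = pair_product_moments(n, f1, f2, s12, [cond])
        # null SNP: covariance with the product within Monte-Carlo error of 0
        assert abs(covs["g"]) < 0.01

    def test_degenerate_conditioner_warns_and_zeroes(self):
        f = FactorStats(1.0, 1.0)
        cond = ConditionerStats("c", 1.0, 0.0, None, 0.0, 0.0)
        with pytest.warns(RuntimeWarning):
            _, w_var, covs = pair_product_moments(100, f, f, 0.5, [cond])
        assert covs["c"] == 0.0
        # falls back to the unconditional normal-theory variance
        assert w_var == pytest.approx(unconditional_product_variance(1.0, 1.0, 1.0, 1.0, 0.5))

    def test_missing_distribution_raises(self):
        f = FactorStats(1.0, 1.0)
        cond = ConditionerStats("c", 1.0, 1.0, None, 0.1, 0.1)
        with pytest.raises(PcssError, match="c"):
            pair_product_moments(100, f, f, 0.5, [cond])


class TestProductVariance:
    def test_binary_formula(self):
        f = FactorStats(0.5, 0.25, is_binary=True)
        # contrive s12 so the product mean is exactly 0.5
        got = product_variance(100, f, FactorStats(1.0, 0.0, is_binary=True), 0.0, [])
        assert got == pytest.approx(0.5 * 0.5 * 100 / 99)

    def test_binary_plugin_value(self):
        # w_mean 0.5 at n=100 -> 0.25 * 100/99 = 0.25252525...
        fa = FactorStats(0.5, 0.25, is_binary=True)
        fb = FactorStats(1.0, 0.0, is_binary=True)
        assert product_variance(100, fa, fb, 0.0, []) == pytest.approx(0.2525252525252525)

    def test_constant_product_is_zero(self):
        fa = FactorStats(2.0, 0.0)
        fb = FactorStats(3.0, 0.0)
        cond = ConditionerStats("g", 1.0, 0.5, GenotypeHwe(0.5), 0.0, 0.0)
        assert product_variance(50, fa, fb, 0.0, [cond]) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_in_conditional_variance(self):
        # the aggregation is non-decreasing in each conditional variance h(w|x)
        from pcssreg.product_moments import _variance_estimate

        xs, ws = GenotypeHwe(0.3).expectation_nodes()
        g = np.array([1.0, 1.5, 2.0])
        hw = np.array([0.5, 0.7, 0.9])
        base = _variance_estimate(xs, ws, g, hw, 200, 1.4, discrete=True)
        for j in range(3):
            bumped = hw.copy()
            bumped[j] += 0.5
            assert _variance_estimate(xs, ws, g, bumped, 200, 1.4, discrete=True) >= base

    def test_median_across_conditioners(self, rng):
        g, y1, y2 = _mc_pair(rng, size=20_000)
        x = rng.standard_normal(20_000) + 0.1 * y1
        n = 20_000
        f1 = FactorStats(*_stats(y1))
        f2 = FactorStats(*_stats(y2))
        s12 = np.cov(y1, y2, ddof=1)[0, 1]
        c1 = ConditionerStats("g", g.mean(), g.var(ddof=1), GenotypeHwe(g.mean() / 2),
                              np.cov(g, y1, ddof=1)[0, 1], np.cov(g, y2, ddof=1)[0, 1])
        c2 = ConditionerStats("x", x.mean(), x.var(ddof=1), Gaussian(x.mean(), x.std(ddof=1)),
                              np.cov(x, y1, ddof=1)[0, 1], np.cov(x, y2, ddof=1)[0, 1])
        both = product_variance(n, f1, f2, s12, [c1, c2])
        lone = sorted(
            [product_variance(n, f1, f2, s12, [c1]), product_variance(n, f1, f2, s12, [c2])]
        )
        assert lone[0] <= both <= lone[1]
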