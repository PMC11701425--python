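import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

import polymax as pm
from polymax.distributions import partial_moment_quad


def quadrature_mixed_moment(model, disc):
    """Independent oracle: numeric quadrature of x f(x) per cell."""
    cum = np.concatenate(([0.0], disc.cumprobs))
    total = 0.0
    for i in range(disc.k):
        if disc.probs[i] <= 1e-12:
            continue
        lo = model.ppf(max(cum[i], 1e-14)) if cum[i] > 0 else model.support[0]
        hi = model.ppf(min(cum[i + 1], 1 - 1e-14)) if cum[i + 1] < 1 else model.support[1]
        total += disc.values[i] * partial_moment_quad(model, lo, hi)
    return total


class TestDiscretization:
    def test_validation(self):
        with pytest.raises(ValueError):
            pm.Discretization([1.0, 1.0], [0.5, 0.5])  # not increasing
        with pytest.raises(ValueError):
            pm.Discretization([1.0, 2.0], [0.7, 0.7])  # sums to 1.4
        with pytest.raises(ValueError):
            pm.Discretization([1.0, 2.0], [-0.1, 1.1])

    def test_summaries(self):
        d = pm.Discretization.equal_prob_cis(4)
        assert d.mean == pytest.approx(2.5)
        assert d.var == pytest.approx(15 / 12)
        np.testing.assert_allclose(d.cumprobs, [0.25, 0.5, 0.75, 1.0])


class TestMixedMoment:
    def test_uniform_k2_direct_integrals(self):
        # 1*int_0^.5 x dx + 2*int_.5^1 x dx = 0.125 + 0.750
        m = pm.make_distribution("uniform")
        d = pm.Discretization.equal_prob_cis(2)
        assert pm.comonotonic_mixed_moment(m, d) == pytest.approx(0.875, abs=1e-14)

    @pytest.mark.parametrize("k", [2, 3, 5, 8])
    def test_exponential_vs_quadrature_oracle(self, k):
        m = pm.make_distribution("exponential", 1.0)
        d = pm.Discretization.equal_prob_cis(k)
        assert pm.comonotonic_mixed_moment(m, d) == pytest.approx(
            quadrature_mixed_moment(m, d), abs=1e-8
        )

    def test_normal_k2_sorted_sample_mc(self):
        m = pm.make_distribution("normal")
        d = pm.Discretization.equal_prob_cis(2)
        analytic = pm.comonotonic_mixed_moment(m, d)
        rng = np.random.default_rng(4)
        n = 10**6
        x = np.sort(rng.standard_normal(n))
        y = np.sort(rng.integers(1, 3, size=n))
        assert analytic == pytest.approx(np.mean(x * y), abs=1e-3)

    def test_zero_prob_cells_skipped(self):
        m = pm.make_distribution("normal")
        d = pm.Discretization.cis([0.5, 0.0, 0.5])
        v = pm.comonotonic_mixed_moment(m, d)
        d2 = pm.Discretization([1.0, 3.0], [0.5, 0.5])
        assert v == pytest.approx(pm.comonotonic_mixed_moment(m, d2), abs=1e-12)


class TestMaxPointPolyserial:
    def test_normal_equal_k2(self):
        m = pm.make_distribution("normal")
        r = pm.max_point_polyserial(m, pm.Discretization.equal_prob_cis(2))
        assert round(r.rho, 4) == 0.7979

    def test_uniform_equal_k10(self):
        m = pm.make_distribution("uniform")
        r = pm.max_point_polyserial(m, pm.Discretization.equal_prob_cis(10))
        assert round(r.rho, 4) == 0.9950
        assert r.rho == pytest.approx(math.sqrt(1 - 1 / 100), abs=1e-12)

    def test_exponential_equal_k2(self):
        m = pm.make_distribution("exponential", 1.0)
        r = pm.max_point_polyserial(m, pm.Discretization.equal_prob_cis(2))
        assert round(r.rho, 4) == 0.6931

    def test_result_consistency(self):
        m = pm.make_distribution("exponential", 1.0)
        r = pm.max_point_polyserial(m, pm.Discretization.equal_prob_cis(5))
        assert 0 < r.rho < 1
        assert np.all(np.diff(r.thresholds) > 0)
        v = r.disc.var
        assert r.covariance == pytest.approx(r.rho * m.std * math.sqrt(v), abs=1e-8)

    def test_zero_variance_error(self):
        m = pm.make_distribution("normal")
        d = pm.Discretization.cis([1.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            pm.max_point_polyserial(m, d)

    def test_pareto_small_alpha_error(self):
        m = pm.make_distribution("pareto", 1.5)
        with pytest.raises(pm.MomentExistenceError):
            pm.max_point_polyserial(m, pm.Discretization.equal_prob_cis(3))

    @pytest.mark.parametrize(
        "spec,k",
        [(("normal",), 4), (("uniform",), 6), (("exponential", 1.0), 3),
         (("pareto", 4.0), 5), (("logistic",), 7), (("power", 2.0), 4)],
        ids=str,
    )
    def test_quadrature_oracle_random_probs(self, spec, k, rng):
        m = pm.make_distribution(*spec)
        probs = rng.dirichlet(np.ones(k))
        d = pm.Discretization.cis(probs)
        r = pm.max_point_polyserial(m, d)
        mixed_oracle = quadrature_mixed_moment(m, d)
        rho_oracle = (mixed_oracle - m.mean * d.mean) / (m.std * math.sqrt(d.var))
        assert 0 < r.rho < 1
        assert r.rho == pytest.approx(rho_oracle, abs=1e-8)


class TestOptimalScores:
    def test_normal_half(self):
        m = pm.make_distribution("normal")
        x = pm.optimal_scores(m, [0.5, 0.5])
        np.testing.assert_allclose(x, [-0.7978845608, 0.7978845608], atol=1e-9)

    def test_uniform_k5(self):
        m = pm.make_distribution("uniform")
        x = pm.optimal_scores(m, np.full(5, 0.2))
        np.testing.assert_allclose(x, [0.1, 0.3, 0.5, 0.7, 0.9], atol=1e-12)

    def test_exponential_thirds_vs_quadrature(self):
        m = pm.make_distribution("exponential", 1.0)
        p = np.full(3, 1 / 3)
        x = pm.optimal_scores(m, p)
        cum = np.array([0.0, 1 / 3, 2 / 3, 1.0])
        for i in range(3):
            lo = m.ppf(cum[i]) if cum[i] > 0 else 0.0
            hi = m.ppf(cum[i + 1]) if cum[i + 1] < 1 else np.inf
            num, _ = integrate.quad(lambda t: t * m.pdf(t), lo, min(hi, 60.0))
            assert x[i] == pytest.approx(num * 3, abs=1e-9)

    def test_mean_preserved_variance_shrunk(self, rng):
        m = pm.make_distribution("logistic")
        p = rng.dirichlet(np.ones(6))
        x = pm.optimal_scores(m, p)
        d = pm.Discretization(x, p)
        assert d.mean == pytest.approx(m.mean, abs=1e-9)
        assert d.var < m.var

    def test_zero_prob_error(self):
        m = pm.make_distribution("normal")
        with pytest.raises(ValueError):
            pm.optimal_scores(m, [0.5, 0.0, 0.5])


class TestCorrWithOptimalScores:
    def test_normal_half(self):
        m = pm.make_distribution("normal")
        assert round(pm.corr_with_optimal_scores(m, [0.5, 0.5]), 4) == 0.7979

    @pytest.mark.parametrize("k", [2, 4, 7])
    def test_uniform_closed_form(self, k):
        m = pm.make_distribution("uniform")
        v = pm.corr_with_optimal_scores(m, np.full(k, 1 / k))
        assert v == pytest.approx(math.sqrt(1 - 1 / k**2), abs=1e-12)

    def test_two_routes_agree(self, rng):
        # sqrt(V)/sigma route vs generic mixed-moment route on the same law
        m = pm.make_distribution("exponential", 2.0)
        p = rng.dirichlet(np.ones(5))
        x = pm.optimal_scores(m, p)
        d = pm.Discretization(x, p)
        assert pm.corr_with_optimal_scores(m, p) == pytest.approx(
            pm.max_point_polyserial(m, d).rho, abs=1e-10
        )

    def test_in_unit_interval(self, rng):
        m = pm.make_distribution("power", 0.7)
        for _ in range(5):
            v = pm.corr_with_optimal_scores(m, rng.dirichlet(np.ones(4)))
            assert 0 < v < 1

    def test_dominates_cis(self, rng):
        m = pm.make_distribution("pareto", 5.0)
        p = rng.dirichlet(np.ones(4))
        cis = pm.max_point_polyserial(m, pm.Discretization.cis(p)).rho
        assert pm.corr_with_optimal_scores(m, p) >= cis - 1e-12


class TestNormalRatios:
    def test_biserial_maximum_at_zero(self):
        assert round(pm.biserial_ratio_normal(0.0), 4) == 0.7979
        assert pm.biserial_ratio_normal(0.0) == pytest.approx(2 * norm.pdf(0), abs=1e-14)

    def test_biserial_tails_vanish(self):
        assert pm.biserial_ratio_normal(8.0) < 1e-6
        assert pm.biserial_ratio_normal(-8.0) < 1e-6

    def test_biserial_symmetry(self):
        for w in [0.3, 1.0, 2.5]:
            assert pm.biserial_ratio_normal(w) == pytest.approx(
                pm.biserial_ratio_normal(-w), abs=1e-12
            )

    def test_biserial_omega_one_mc_oracle(self):
        rng = np.random.default_rng(11)
        z = rng.standard_normal(2 * 10**6)
        x2 = (z >= 1.0).astype(float)
        mc = np.corrcoef(z, x2)[0, 1]
        assert pm.biserial_ratio_normal(1.0) == pytest.approx(mc, abs=2e-3)

    def test_table1_values(self):
        assert round(pm.normal_ratio(np.full(3, 1 / 3)), 4) == 0.8906
        assert round(pm.normal_ratio(np.full(7, 1 / 7)), 4) == 0.9581

    def test_degenerate_error(self):
        with pytest.raises(ValueError):
            pm.normal_ratio([1.0, 0.0, 0.0])

    def test_k2_consistency_with_biserial(self):
        for w in [-1.2, 0.0, 0.4, 2.0]:
            p = norm.sf(w)
            assert pm.normal_ratio([1 - p, p]) == pytest.approx(
                pm.biserial_ratio_normal(w), abs=1e-12
            )

    def test_matches_generic_machinery(self, rng):
        m = pm.make_distribution("normal")
        p = rng.dirichlet(np.ones(5))
        d = pm.Discretization.cis(p)
        assert pm.normal_ratio(p) == pytest.approx(
            pm.max_point_polyserial(m, d).rho, abs=1e-10
        )


class TestAttainableBounds:
    def test_lognormal_sigma2(self):
        m1 = pm.make_distribution("lognormal", 0.0, 1.0)
        m2 = pm.make_distribution("lognormal", 0.0, 2.0)
        lo, hi = pm.attainable_bounds(m1, m2)
        assert round(hi, 3) == 0.666
        assert round(lo, 3) == -0.090

    def test_lognormal_same_type(self):
        m1 = pm.make_distribution("lognormal", 0.0, 1.0)
        lo, hi = pm.attainable_bounds(m1, m1)
        assert hi == pytest.approx(1.0, abs=1e-12)
        assert lo == pytest.approx(-0.368, abs=5e-4)

    def test_quadrature_matches_closed_form(self):
        m1 = pm.make_distribution("lognormal", 0.0, 1.0)
        m2 = pm.make_distribution("lognormal", 0.0, 2.0)
        cf = pm.attainable_bounds(m1, m2)
        qd = pm.attainable_bounds(m1, m2, method="quadrature")
        assert qd[0] == pytest.approx(cf[0], abs=5e-4)
        assert qd[1] == pytest.approx(cf[1], abs=5e-4)

    def test_same_model_max_one(self):
        for spec in [("normal",), ("exponential", 1.0), ("power", 2.0)]:
            m = pm.make_distribution(*spec)
            lo, hi = pm.attainable_bounds(m, m)
            assert hi == pytest.approx(1.0, abs=1e-9)
            assert lo < 0

    def test_symmetric_family_attains_minus_one(self):
        m = pm.make_distribution("normal")
        lo, _ = pm.attainable_bounds(m, m)
        assert lo == pytest.approx(-1.0, abs=1e-9)

    def test_nonexistent_variance_error(self):
        with pytest.raises(pm.MomentExistenceError):
            pm.attainable_bounds(
                pm.make_distribution("pareto", 1.5), pm.make_distribution("normal")
            )


class TestEmpiricalMaxCorr:
    def test_monotone_transform_already_comonotone(self, rng):
        # an increasing transform of x is already comonotone with it, so the
        # sorted-sample correlation equals the plain correlation and is
        # invariant under joint permutation of the inputs
        x = rng.standard_normal(500)
        y = np.exp(x)
        assert pm.empirical_max_corr(rng.permutation(x), rng.permutation(y)) == pytest.approx(
            pm.empirical_max_corr(x, y), abs=1e-12
        )
        assert pm.empirical_max_corr(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_tiny_exact(self):
        assert pm.empirical_max_corr([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)

    def test_normal_vs_six_level_ordinal(self):
        rng = np.random.default_rng(6)
        n = 10**6
        x = rng.standard_normal(n)
        y = rng.integers(1, 7, size=n).astype(float)
        analytic = pm.normal_ratio(np.full(6, 1 / 6))  # .9520
        assert pm.empirical_max_corr(x, y) == pytest.approx(analytic, abs=2e-3)

    def test_errors(self):
        with pytest.raises(ValueError):
            pm.empirical_max_corr([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            pm.empirical_max_corr([1.0], [2.0])
        with pytest.raises(ValueError):
            pm.empirical_max_corr([1.0, 1.0], [1.0, 2.0])
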