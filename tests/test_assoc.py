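"""Association tests, multiple testing and meta-analysis against oracles."""

import numpy as np
import pytest
from scipy import stats
from statsmodels.stats.meta_analysis import combine_effects

from cogexome.assoc import (
    bh_fdr,
    bonferroni_threshold,
    firth_logistic,
    genomic_lambda,
    ivw_random_effects_meta,
    linear_burden_test,
    logistic_burden_test,
)
from cogexome.simulate import simulate_binary_logistic


class TestLinear:
    def test_perfect_fit(self):
        b = np.array([0.0, 1, 2, 0, 1, 2, 0, 1])
        res = linear_burden_test(b, b)
        assert res.beta == pytest.approx(1.0)
        assert res.p < 1e-12

    def test_matches_normal_equations_on_toy(self):
        rng = np.random.default_rng(0)
        n = 12
        b = rng.binomial(1, 0.4, n).astype(float)
        C = rng.normal(size=(n, 2))
        y = 0.3 * b + C @ [0.5, -0.2] + rng.normal(size=n)
        res = linear_burden_test(b, y, C)
        X = np.column_stack([np.ones(n), b, C])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (n - 4)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert res.beta == pytest.approx(beta[1], abs=1e-10)
        assert res.se == pytest.approx(se, abs=1e-10)
        tq = stats.t.ppf(0.975, n - 4)
        assert res.ci_low == pytest.approx(beta[1] - tq * se, abs=1e-10)

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(2000):
            b = rng.binomial(1, 0.2, 100).astype(float)
            if b.sum() == 0:
                continue
            ps.append(linear_burden_test(b, rng.normal(size=100)).p)
        _, p = stats.kstest(ps, "uniform")
        assert p > 0.01

    def test_zero_variance_burden_rejected(self):
        with pytest.raises(ValueError, match="no carriers"):
            linear_burden_test(np.zeros(10), np.arange(10.0))

    def test_collinear_covariate_rejected(self):
        b = np.array([0.0, 1, 0, 1, 0, 1])
        with pytest.raises(ValueError, match="collinear"):
            linear_burden_test(b, np.arange(6.0), covariates=2 * b)


class TestLogistic:
    def test_two_by_two_equals_cross_product_ratio(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            b = rng.binomial(1, 0.3, 300).astype(float)
            y = rng.binomial(1, np.where(b > 0, 0.5, 0.25)).astype(float)
            a = np.sum((b == 1) & (y == 1))
            bb = np.sum((b == 1) & (y == 0))
            c = np.sum((b == 0) & (y == 1))
            d = np.sum((b == 0) & (y == 0))
            if min(a, bb, c, d) == 0:
                continue
            res = logistic_burden_test(b, y)
            assert res.odds_ratio == pytest.approx((a * d) / (bb * c), rel=1e-5)

    def test_null_burden_ci_covers_one(self):
        rng = np.random.default_rng(3)
        b = rng.binomial(1, 0.3, 2000).astype(float)
        y = rng.binomial(1, 0.4, 2000).astype(float)
        res = logistic_burden_test(b, y)
        assert res.ci_low < 0 < res.ci_high  # log-OR CI covers 0

    def test_separation_is_flagged(self):
        b = np.r_[np.ones(10), np.zeros(90)]
        y = (b > 0).astype(float)
        res = logistic_burden_test(b, y)
        assert not res.converged

    def test_known_or_recovered(self):
        rng = np.random.default_rng(4)
        b = rng.binomial(1, 0.01, 30_000).astype(float)
        y = simulate_binary_logistic(b, np.log(4.812), prevalence=0.1, seed=5)
        res = logistic_burden_test(b, y)
        assert abs(res.beta - np.log(4.812)) < 2 * res.se

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            logistic_burden_test(np.array([0.0, 1]), np.array([1.0, 1]))


class TestFirth:
    @pytest.mark.parametrize("n_carrier,n_total", [(5, 50), (10, 100), (3, 30)])
    def test_finite_under_complete_separation(self, n_carrier, n_total):
        b = np.r_[np.ones(n_carrier), np.zeros(n_total - n_carrier)]
        y = (b > 0).astype(float)
        res = firth_logistic(b, y)
        assert np.isfinite(res.beta) and np.isfinite(res.se)

    def test_finite_under_quasi_separation_with_covariate(self):
        rng = np.random.default_rng(6)
        n = 200
        b = np.r_[np.ones(8), np.zeros(n - 8)]
        y = np.where(b > 0, 1.0, rng.binomial(1, 0.3, n))
        res = firth_logistic(b, y, covariates=rng.normal(size=n))
        assert np.isfinite(res.beta) and np.isfinite(res.se)

    def test_agrees_with_plain_logistic_asymptotically(self):
        rng = np.random.default_rng(7)
        n = 50_000
        b = rng.binomial(1, 0.3, n).astype(float)
        y = simulate_binary_logistic(b, 0.8, prevalence=0.3, seed=8)
        plain = logistic_burden_test(b, y)
        firth = firth_logistic(b, y)
        assert firth.beta == pytest.approx(plain.beta, rel=0.01)

    def test_two_by_two_zero_cell_matches_haldane_correction(self):
        y = np.r_[np.ones(10), np.zeros(190)]
        b = np.zeros(200)
        b[:8] = 1  # all 8 carriers among the first 10 cases -> zero cell
        a = np.sum((b == 1) & (y == 1))
        bb = np.sum((b == 1) & (y == 0))
        c = np.sum((b == 0) & (y == 1))
        d = np.sum((b == 0) & (y == 0))
        assert bb == 0
        expected = np.log(((a + 0.5) * (d + 0.5)) / ((bb + 0.5) * (c + 0.5)))
        res = firth_logistic(b, y)
        assert res.beta == pytest.approx(expected, abs=1e-5)

    def test_plr_p_available(self):
        rng = np.random.default_rng(9)
        b = rng.binomial(1, 0.2, 500).astype(float)
        y = simulate_binary_logistic(b, 1.0, prevalence=0.2, seed=10)
        res = firth_logistic(b, y, p_method="plr")
        assert 0 < res.p <= 1


class TestMultipleTesting:
    def test_bonferroni_reproduces_printed_thresholds(self):
        cases = [
            (15_782, 3.17e-6),
            (15_798, 3.16e-6),
            (11_905, 4.20e-6),
            (43_485, 1.15e-6),
            (3_150, 1.59e-5),
        ]
        for n_tests, printed in cases:
            assert bonferroni_threshold(0.05, n_tests) == pytest.approx(printed, rel=5e-3)
        assert bonferroni_threshold(1.0, 1) == 1.0

    def test_bh_single_p(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_bh_hand_computed_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_bh_matches_brute_force(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            m = p.size
            order = np.argsort(p)
            # independent definition: q_(i) = min_{j>=i} m * p_(j) / j
            q_sorted = np.minimum.accumulate(
                (m * p[order] / np.arange(1, m + 1))[::-1]
            )[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(q_sorted, 1.0)
            assert np.allclose(bh_fdr(p), expected)


class TestGenomicLambda:
    def test_constant_half_gives_exactly_one(self):
        assert genomic_lambda(np.full(100, 0.5)) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_p_values_give_unit_lambda(self):
        # at 100,000 draws the sampling SD of lambda is ~0.007, so the
        # [0.95, 1.05] band is ~7 SD wide and the check is not flaky
        rng = np.random.default_rng(11)
        lam = genomic_lambda(rng.uniform(size=100_000))
        assert 0.95 <= lam <= 1.05

    def test_halving_p_increases_lambda(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=1000)
        assert genomic_lambda(p / 2) > genomic_lambda(p)


class TestMeta:
    def test_identical_studies(self):
        res = ivw_random_effects_meta([0.5, 0.5], [0.1, 0.1])
        assert res.beta == pytest.approx(0.5)
        assert res.se == pytest.approx(0.1 / np.sqrt(2))
        assert res.notes["tau2"] == 0.0

    def test_heterogeneous_pair_inflates_se(self):
        betas, ses = np.array([0.2, 1.0]), np.array([0.1, 0.1])
        res = ivw_random_effects_meta(betas, ses)
        w = 1 / ses**2
        se_fixed = np.sqrt(1 / w.sum())
        assert res.notes["tau2"] > 0
        assert res.se > se_fixed

    def test_matches_statsmodels_dersimonian_laird(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            k = rng.integers(2, 8)
            betas = rng.normal(0.3, 0.3, k)
            ses = rng.uniform(0.05, 0.4, k)
            mine = ivw_random_effects_meta(betas, ses)
            ref = combine_effects(betas, ses**2, method_re="dl")
            table = ref.summary_frame()
            # statsmodels leaves the DL tau2 moment estimate untruncated; the
            # standard estimator clips it at 0, where RE reduces to fixed-effect
            row = "random effect" if ref.tau2 > 0 else "fixed effect"
            assert mine.beta == pytest.approx(table.loc[row, "eff"], abs=1e-8)
            assert mine.se == pytest.approx(table.loc[row, "sd_eff"], abs=1e-8)

    def test_concordant_replication_strengthens_evidence(self):
        studies = ([1.571, 1.604], [0.47, 0.39])
        combined = ivw_random_effects_meta(*studies)
        p_individual = [2 * stats.norm.sf(abs(b / s)) for b, s in zip(*studies)]
        assert combined.p < min(p_individual)

    def test_single_study_warns_and_passes_through(self):
        with pytest.warns(UserWarning):
            res = ivw_random_effects_meta([0.3], [0.1])
        assert res.beta == 0.3 and res.se == 0.1


def test_linear_and_logistic_type_one_error_calibrated():
    rng = np.random.default_rng(14)
    n_reps, n = 2000, 400
    rej_lin = {0.05: 0, 0.01: 0}
    rej_log = {0.05: 0, 0.01: 0}
    done = 0
    for _ in range(n_reps):
        b = rng.binomial(1, 0.1, n).astype(float)
        if b.sum() == 0:
            continue
        y = rng.normal(size=n)
        yb = rng.binomial(1, 0.3, n).astype(float)
        p_lin = linear_burden_test(b, y).p
        res_log = logistic_burden_test(b, yb)
        if not res_log.converged:
            continue
        done += 1
        for a in rej_lin:
            rej_lin[a] += p_lin < a
            rej_log[a] += res_log.p < a
    # 3.29 SE = 99.9% band per check; four checks give a <0.5% joint
    # false-alarm rate under correct calibration
    for a in (0.05, 0.01):
        ci = 3.29 * np.sqrt(a * (1 - a) / done)
        assert abs(rej_lin[a] / done - a) < ci + 0.002
        assert abs(rej_log[a] / done - a) < ci + 0.005  # Wald p slightly liberal at n=400
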