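"""Spline regression, threshold discovery, ROC metrics and classical tests."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.special import expit, logit

from pnms import (
    confusion_metrics,
    find_inflection,
    fit_logistic,
    knots_from_percentiles,
    odds_ratio_report,
    pearson_chi2,
    rcs_basis,
    rcs_logistic_curve,
    roc_youden,
    select_rcs_by_bic,
)
from pnms.stats import ancova, fisher_exact, g_test, pearson_corr, two_group_test


class TestRcsBasis:
    KNOTS = np.array([-1.0, 0.2, 1.5])

    def test_zero_below_first_knot(self):
        x = np.linspace(-5, -1.0, 20)
        b = rcs_basis(x, self.KNOTS)
        assert np.allclose(b[:, 1], 0.0)
        assert np.allclose(b[:, 0], x)

    def test_linear_tail(self):
        # second difference of s(x) vanishes far beyond the last knot
        span = self.KNOTS[-1] - self.KNOTS[0]
        x0 = self.KNOTS[-1] + 5 * span
        h = 0.01
        s = rcs_basis(np.array([x0 - h, x0, x0 + h]), self.KNOTS)[:, 1]
        assert abs(s[0] - 2 * s[1] + s[2]) < 1e-8

    def test_direct_formula_oracle(self, rng):
        t1, t2, t3 = self.KNOTS
        x = rng.uniform(-3, 3, 20)
        got = rcs_basis(x, self.KNOTS)[:, 1]
        plus = lambda u: np.where(u > 0, u, 0.0) ** 3
        want = (
            plus(x - t1)
            - plus(x - t2) * (t3 - t1) / (t3 - t2)
            + plus(x - t3) * (t2 - t1) / (t3 - t2)
        ) / (t3 - t1) ** 2
        assert np.allclose(got, want, atol=1e-12)

    def test_duplicate_knots_rejected(self):
        with pytest.raises(ValueError):
            rcs_basis(np.arange(5.0), np.array([0.0, 0.0, 1.0]))


class TestKnots:
    def test_1_to_100(self):
        knots = knots_from_percentiles(np.arange(1.0, 101.0))
        assert np.allclose(knots, [10.9, 50.5, 90.1])

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            knots_from_percentiles(np.ones(50))

    def test_median_knot_is_sample_median(self, rng):
        x = rng.normal(size=101)
        knots = knots_from_percentiles(x)
        assert knots[1] == pytest.approx(np.median(x))


class TestLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0] * 30 + [0.0] * 10)
        fit = fit_logistic(np.ones((40, 1)), y)
        assert fit.params[0] == pytest.approx(logit(0.75), abs=1e-6)

    def test_consistency(self, rng):
        x = rng.normal(size=5000)
        y = (rng.random(5000) < expit(0.2 + 1.0 * x)).astype(float)
        fit = fit_logistic(np.column_stack([np.ones(5000), x]), y)
        assert 0.9 <= fit.params[1] <= 1.1

    def test_bic_formula(self, rng):
        x = rng.normal(size=200)
        y = (rng.random(200) < expit(x)).astype(float)
        fit = fit_logistic(np.column_stack([np.ones(200), x]), y)
        assert fit.bic == pytest.approx(-2 * fit.loglik + 2 * np.log(200))

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones((10, 1)), np.ones(10))

    def test_separation_flagged(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = x.copy()
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_logistic(np.column_stack([np.ones(20), x]), y)
        assert fit.separation


class TestOddsRatio:
    def test_binary_predictor_cross_product(self):
        # 2x2 table (20, 4 / 1, 5): OR = (20*5)/(4*1) = 25
        x = np.r_[np.ones(20), np.zeros(4), np.ones(1), np.zeros(5)]
        y = np.r_[np.ones(24), np.zeros(6)]
        rep = odds_ratio_report(x, y, scale=1.0)
        assert rep["or"] == pytest.approx(25.0, rel=1e-4)

    def test_scaling_reparameterization(self, rng):
        x = rng.normal(size=200)
        y = (rng.random(200) < expit(x)).astype(float)
        r1 = odds_ratio_report(x, y, scale=1.0)
        r2 = odds_ratio_report(x, y, scale=0.5)
        assert np.log(r2["or"]) == pytest.approx(0.5 * np.log(r1["or"]), rel=1e-8)

    def test_wald_ci_coverage_under_null(self):
        covered = 0
        reps = 300
        for seed in range(reps):
            g = np.random.default_rng(seed)
            x = g.normal(size=80)
            y = (g.random(80) < 0.5).astype(float)
            rep = odds_ratio_report(x, y)
            covered += rep["ci_low"] <= 1.0 <= rep["ci_high"]
        assert 0.91 <= covered / reps <= 0.99


class TestRcsCurve:
    def test_planted_u_shape_detected(self):
        hits = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            x = g.normal(size=2000)
            y = (g.random(2000) < expit(-0.5 + 0.8 * x ** 2)).astype(float)
            fit = rcs_logistic_curve(x, y)
            hits += fit.p_nonlinearity < 0.05
        assert hits >= 18  # >= 90% power

    def test_bic_prefers_linear_on_linear_truth(self):
        wins = 0
        for seed in range(20):
            g = np.random.default_rng(100 + seed)
            x = g.normal(size=2000)
            y = (g.random(2000) < expit(0.3 + 0.8 * x)).astype(float)
            spline = rcs_logistic_curve(x, y)
            lin = rcs_logistic_curve(x, y, linear=True)
            wins += select_rcs_by_bic([spline, lin]) is lin
        assert wins >= 16  # >= 80%

    def test_reference_or_is_one(self, rng):
        x = rng.normal(size=500)
        y = (rng.random(500) < expit(x)).astype(float)
        fit = rcs_logistic_curve(x, y, reference_x=float(np.median(x)))
        i = np.argmin(np.abs(fit.grid_x - fit.reference_x))
        assert fit.grid_or[i] == pytest.approx(1.0, abs=0.05)

    def test_select_requires_same_n(self, rng):
        x = rng.normal(size=200)
        y = (rng.random(200) < 0.5).astype(float)
        f1 = rcs_logistic_curve(x, y)
        f2 = rcs_logistic_curve(x[:150], y[:150])
        with pytest.raises(ValueError):
            select_rcs_by_bic([f1, f2])
        assert select_rcs_by_bic([f1]) is f1


class TestInflection:
    def test_quadratic_vertex_recovered(self):
        g = np.random.default_rng(7)
        x = g.uniform(-1, 1.6, 4000)
        y = (g.random(4000) < expit(2.0 * (x - 0.3) ** 2 - 0.5)).astype(float)
        fit = rcs_logistic_curve(x, y)
        res = find_inflection(fit)
        step = fit.grid_x[1] - fit.grid_x[0]
        assert res.shape == "U"
        assert min(abs(p - 0.3) for p in res.points) <= 3 * step

    def test_monotone_curve_gives_elbow_not_extremum(self):
        g = np.random.default_rng(11)
        x = g.normal(size=3000)
        y = (g.random(3000) < expit(0.2 + 1.2 * x)).astype(float)
        res = find_inflection(rcs_logistic_curve(x, y))
        assert res.shape in ("monotone", "L")
        assert res.kinds in ([], ["elbow"])

    def test_flat_curve_no_inflection(self, rng):
        x = rng.normal(size=500)
        y = (rng.random(500) < 0.5).astype(float)
        fit = rcs_logistic_curve(x, y)
        fit.grid_logodds = np.zeros_like(fit.grid_logodds)
        res = find_inflection(fit)
        assert res.shape == "flat" and res.reference is None


class TestRocYouden:
    def test_perfect_separation(self):
        score = np.r_[np.zeros(5), np.ones(5)]
        y = score.copy()
        ev = roc_youden(score, y)
        assert ev.auc == pytest.approx(1.0)
        assert ev.youden_j == pytest.approx(1.0)

    def test_brute_force_oracle(self):
        """Chosen threshold and J match exhaustive midpoint enumeration."""
        for seed in range(30):
            g = np.random.default_rng(seed)
            score = np.round(g.normal(size=50), 2)  # force ties
            y = (g.random(50) < 0.4).astype(float)
            if y.min() == y.max():
                continue
            ev = roc_youden(score, y)
            uniq = np.unique(score)
            mids = np.r_[uniq[0] - 1, (uniq[:-1] + uniq[1:]) / 2, uniq[-1] + 1]
            best_j, best_t = -np.inf, None
            for t in mids:
                tp = np.sum((score >= t) & (y == 1))
                fp = np.sum((score >= t) & (y == 0))
                j = tp / y.sum() - fp / (y == 0).sum()
                if j > best_j + 1e-12:
                    best_j, best_t = j, t
            assert ev.youden_j == pytest.approx(best_j, abs=1e-12)
            # same confusion table as the oracle threshold
            assert np.sum((score >= ev.threshold) & (y == 1)) == np.sum(
                (score >= best_t) & (y == 1)
            )

    def test_label_flip_symmetry(self, rng):
        score = rng.normal(size=80)
        y = (rng.random(80) < 0.5).astype(float)
        assert roc_youden(-score, y).auc == pytest.approx(1 - roc_youden(score, y).auc)

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        score = rng.normal(size=200)
        y = (rng.random(200) < expit(score)).astype(float)
        assert roc_youden(score, y).auc == pytest.approx(roc_auc_score(y, score), abs=1e-10)

    def test_constant_score_degenerate(self):
        ev = roc_youden(np.ones(10), np.r_[np.ones(5), np.zeros(5)])
        assert ev.auc == 0.5 and not ev.threshold_defined


class TestConfusionMetrics:
    def test_reconstructed_outcome_table(self):
        # 21 seizure-free / 9 not, sensitivity 0.95, specificity 0.56
        m = confusion_metrics(20, 4, 1, 5)
        assert m["sensitivity"] == pytest.approx(0.9524, abs=1e-4)
        assert m["specificity"] == pytest.approx(0.5556, abs=1e-4)
        assert m["overall_accuracy"] == pytest.approx(0.8333, abs=1e-4)
        assert m["balanced_accuracy"] == pytest.approx(0.7540, abs=1e-4)

    def test_perfect_classifier(self):
        m = confusion_metrics(10, 0, 0, 10)
        assert all(m[k] == 1.0 for k in
                   ("sensitivity", "specificity", "balanced_accuracy", "overall_accuracy"))

    def test_prevalence_weights_give_overall_accuracy(self):
        m = confusion_metrics(20, 4, 1, 5, weights=(0.7, 0.3))
        assert m["weighted_accuracy"] == pytest.approx(m["overall_accuracy"], abs=1e-10)


class TestCategorical:
    def test_chi2_outcome_table(self):
        stat, p = pearson_chi2(np.array([[20, 1], [4, 5]]))
        assert stat == pytest.approx(10.16, abs=0.005)
        assert p == pytest.approx(0.001, abs=0.001)

    def test_chi2_independent_table_zero(self):
        stat, _ = pearson_chi2(np.array([[10, 10], [10, 10]]))
        assert stat == 0.0

    def test_chi2_matches_expected_count_formula(self, rng):
        for _ in range(100):
            t = rng.integers(1, 40, size=(2, 2)).astype(float)
            stat, p = pearson_chi2(t)
            exp = np.outer(t.sum(1), t.sum(0)) / t.sum()
            want = ((t - exp) ** 2 / exp).sum()
            assert stat == pytest.approx(want, rel=1e-10)

    def test_fisher_matches_hypergeometric_enumeration(self):
        t = np.array([[20, 1], [4, 5]])
        _, p = fisher_exact(t)
        # enumerate all tables with the same margins; sum P of those
        # no more probable than the observed one
        r1, c1, n = 21, 24, 30
        obs = sps.hypergeom.pmf(20, n, r1, c1)
        total = sum(
            sps.hypergeom.pmf(k, n, r1, c1)
            for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
            if sps.hypergeom.pmf(k, n, r1, c1) <= obs * (1 + 1e-9)
        )
        assert p == pytest.approx(total, rel=1e-6)

    def test_g_test_sanity(self):
        g, p = g_test(np.array([[20, 1], [4, 5]]))
        assert g > 0 and 0 < p < 0.05


class TestAuxiliary:
    def test_identical_groups(self):
        a = np.arange(10.0)
        res = two_group_test(a, a, "t")
        assert res["statistic"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_t_type_i_error(self):
        rej = 0
        for seed in range(500):
            g = np.random.default_rng(seed)
            rej += two_group_test(g.normal(size=30), g.normal(size=30), "t")["p"] < 0.05
        assert 0.03 <= rej / 500 <= 0.07

    def test_pearson_linear(self):
        x = np.arange(20.0)
        r, p = pearson_corr(x, 3 * x - 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_ancova_detects_adjusted_difference(self, rng):
        cov = rng.normal(size=100)
        grp = np.r_[np.zeros(50), np.ones(50)]
        y = 2.0 * cov + 1.0 * grp + rng.normal(0, 0.5, 100)
        res = ancova(y, grp, cov)
        assert res["p"] < 1e-6

    def test_rcs_nonlinearity_type_i_error(self):
        """Under a truly linear logit the nonlinearity test keeps its size."""
        rej = 0
        reps = 500
        for seed in range(reps):
            g = np.random.default_rng(10_000 + seed)
            x = g.normal(size=2000)
            y = (g.random(2000) < expit(0.3 + 0.8 * x)).astype(float)
            rej += rcs_logistic_curve(x, y).p_nonlinearity < 0.05
        assert 0.03 <= rej / reps <= 0.07
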