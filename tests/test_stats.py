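"""Normality screening and discriminant-analysis tests."""

import numpy as np
import pytest
from scipy.stats import f as f_dist
from scipy.stats import norm

from pclung.stats import (
    DiscriminantModel,
    classify,
    error_rates,
    fit_discriminant,
    ks_normality,
    score,
    variance_equality,
)


class TestKSNormality:
    def test_critical_value_convention(self, rng):
        res = ks_normality(rng.normal(size=20))
        assert res.critical_value == pytest.approx(0.94 / np.sqrt(20))
        assert res.critical_value == pytest.approx(0.2101, abs=2e-4)
        res25 = ks_normality(rng.normal(size=25))
        assert res25.critical_value == pytest.approx(0.1884, abs=5e-4)

    def test_stairstep_geometry_with_fixed_parameters(self):
        # exact normal quantiles at (i - 0.5)/n against the fixed N(0,1)
        # CDF leave a maximal deviation of exactly 0.5/n
        n = 20
        sample = norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        res = ks_normality(sample, mean=0.0, sd=1.0)
        assert res.k_stat == pytest.approx(0.5 / n, abs=1e-12)

    def test_bimodal_sample_rejected(self, rng):
        sample = np.concatenate([rng.normal(-5, 0.1, 50), rng.normal(5, 0.1, 50)])
        assert not ks_normality(sample).accept

    def test_normal_sample_accepted(self, rng):
        assert ks_normality(rng.normal(size=50)).accept

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality(np.ones(20))

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality(np.arange(4.0))

    def test_statistic_matches_lilliefors(self, rng):
        from statsmodels.stats.diagnostic import lilliefors

        sample = rng.normal(size=40)
        res = ks_normality(sample, convention="lilliefors")
        ref_stat, _ = lilliefors(sample, dist="norm")
        assert res.k_stat == pytest.approx(ref_stat, abs=1e-10)

    def test_type_one_rate_is_conservative(self, rng):
        # the c = 0.94 convention is stricter than Lilliefors alpha = 0.05
        rejections = 0
        reps = 400
        for _ in range(reps):
            rejections += not ks_normality(rng.normal(size=25)).accept
        assert rejections / reps < 0.05


class TestVarianceEquality:
    def test_equal_variances(self):
        assert variance_equality(2.0, 2.0, 25, 25) == "equal"

    def test_grossly_unequal(self):
        assert variance_equality(100.0, 1.0, 25, 25) == "unequal"

    def test_type_one_calibration(self, rng):
        n, reps = 25, 10_000
        v1 = rng.normal(size=(reps, n)).var(axis=1, ddof=1)
        v2 = rng.normal(size=(reps, n)).var(axis=1, ddof=1)
        f = v1 / v2
        lo, hi = f_dist.ppf([0.025, 0.975], n - 1, n - 1)
        rate = np.mean((f < lo) | (f > hi))
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            variance_equality(0.0, 1.0, 10, 10)
        with pytest.raises(ValueError):
            variance_equality(1.0, 1.0, 1, 10)


class TestFitDiscriminant:
    def test_same_data_gives_ldf_equal_means(self, rng):
        x = rng.normal(size=30)
        model = fit_discriminant(x, x)
        assert model.form == "ldf"
        assert model.mean1 == model.mean2

    def test_pooled_variance_equal_sizes(self, rng):
        x1 = rng.normal(0, 1, 25)
        x2 = rng.normal(0, 2, 25)
        model = fit_discriminant(x1, x2, form="ldf")
        assert model.pooled_var == pytest.approx((model.var1 + model.var2) / 2)

    def test_unequal_variances_select_qdf(self, rng):
        x1 = rng.normal(0, 1, 25)
        x2 = rng.normal(0, 10, 25)
        assert fit_discriminant(x1, x2).form == "qdf"

    def test_parameter_recovery_from_simulated_features(self):
        from pclung.synth import FeatureSimSpec, sample_features

        spec = FeatureSimSpec(n_per_class=200, seed=7)
        table = sample_features(spec)
        for label in ("NL", "LC"):
            mu, sd = spec.class_params[label]["homogeneity"]
            vals = table.loc[table["class"] == label, "homogeneity"]
            se = sd / np.sqrt(len(vals))
            assert abs(vals.mean() - mu) < 3 * se

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_discriminant(np.ones(10), np.arange(10.0))


class TestScoreAndClassify:
    def _model(self, form="qdf"):
        return DiscriminantModel(
            mean1=2.0, mean2=-1.0, var1=1.5, var2=0.5, n1=25, n2=20, form=form
        )

    def test_ldf_zero_at_midpoint(self):
        m = self._model("ldf")
        assert score(m, (m.mean1 + m.mean2) / 2) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("form", ["ldf", "qdf"])
    def test_score_is_log_density_ratio(self, form):
        m = self._model(form)
        s1 = np.sqrt(m.pooled_var if form == "ldf" else m.var1)
        s2 = np.sqrt(m.pooled_var if form == "ldf" else m.var2)
        for x0 in (-2.0, 0.3, 4.5):
            direct = norm(m.mean1, s1).logpdf(x0) - norm(m.mean2, s2).logpdf(x0)
            assert score(m, x0) == pytest.approx(direct, abs=1e-10)

    def test_swapping_classes_negates_score(self):
        m = self._model()
        swapped = DiscriminantModel(
            mean1=m.mean2, mean2=m.mean1, var1=m.var2, var2=m.var1, n1=m.n2, n2=m.n1, form="qdf"
        )
        for x0 in (-1.0, 0.0, 2.5):
            assert score(swapped, x0) == pytest.approx(-score(m, x0), abs=1e-12)

    def test_ldf_equals_qdf_for_equal_variances(self, rng):
        x1 = rng.normal(0, 1, 40)
        x2 = rng.normal(2, 1, 40)
        # force equal variances so both forms describe the same densities
        m_ldf = fit_discriminant(x1, x2, form="ldf")
        v = m_ldf.pooled_var
        m_q = DiscriminantModel(
            mean1=m_ldf.mean1, mean2=m_ldf.mean2, var1=v, var2=v, n1=40, n2=40, form="qdf"
        )
        x = np.linspace(-3, 5, 50)
        assert np.abs(score(m_ldf, x) - score(m_q, x)).max() < 1e-10

    def test_classification_threshold(self):
        m = self._model("ldf")
        assert classify(m, 10.0, 1.0) == 1
        assert classify(m, 10.0, 1e30) == 2

    def test_boundary_assigned_to_class_one(self):
        m = self._model("ldf")
        mid = (m.mean1 + m.mean2) / 2  # score exactly 0 = ln(1)
        assert classify(m, mid, 1.0) == 1

    def test_monotone_in_cost_ratio(self, rng):
        m = self._model("ldf")
        x = rng.normal(0, 2, 100)
        prev = classify(m, x, 0.1)
        for c in (1.0, 10.0, 100.0):
            cur = classify(m, x, c)
            assert np.all(cur >= prev)  # raising C never moves 2 -> 1
            prev = cur

    def test_invalid_cost_ratio(self):
        with pytest.raises(ValueError):
            classify(self._model(), 0.0, 0.0)


class TestErrorRates:
    def test_perfect_separation(self):
        m = fit_discriminant([10.0, 11.0, 12.0], [0.0, 1.0, 2.0], form="ldf")
        err = error_rates(m, [10.5, 11.5], [0.5, 1.5])
        assert err.delta == 0.0 and err.beta == 0.0

    def test_empty_class_rejected(self):
        m = fit_discriminant([10.0, 11.0], [0.0, 1.0], form="ldf")
        with pytest.raises(ValueError):
            error_rates(m, [], [1.0])

    def test_bayes_error_two_unit_normals(self, rng):
        # means 0 and 2, SD 1, C=1: both error rates approach Phi(-1)
        n = 100_000
        m = DiscriminantModel(mean1=2.0, mean2=0.0, var1=1.0, var2=1.0, n1=n, n2=n, form="ldf")
        err = error_rates(m, rng.normal(2, 1, n), rng.normal(0, 1, n))
        assert err.delta == pytest.approx(norm.cdf(-1), abs=0.01)
        assert err.beta == pytest.approx(norm.cdf(-1), abs=0.01)
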