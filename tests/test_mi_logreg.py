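"""Bayesian logistic imputation: fit, posterior draws, imputation, pooling."""

import numpy as np
import pytest

from rrmice import (
    LogisticFit,
    apply_selection,
    augment_observations,
    draw_beta,
    fit_bayes_logistic,
    impute_once,
    mice_estimate,
    multiple_impute,
    point_biserial,
    pool_estimates,
)


class TestFit:
    def test_matches_statsmodels_mle(self, rng):
        # independent oracle: unpenalized ML fit from statsmodels
        import statsmodels.api as sm

        x = rng.standard_normal(400)
        y = (rng.random(400) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(int)
        fit = fit_bayes_logistic(x[:, None], y, ridge=0.0)
        sm_fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        np.testing.assert_allclose(fit.beta_hat, sm_fit.params, atol=1e-6)
        np.testing.assert_allclose(
            fit.cov_hat, sm_fit.cov_params(), rtol=1e-4, atol=1e-8
        )

    def test_constant_response_raises(self):
        with pytest.raises(ValueError):
            fit_bayes_logistic(np.arange(10.0)[:, None], np.ones(10))

    def test_independent_balanced_data_gives_null_coefficients(self, rng):
        x = rng.standard_normal(50_000)
        y = rng.integers(0, 2, 50_000)
        fit = fit_bayes_logistic(x[:, None], y)
        assert np.allclose(fit.beta_hat, 0.0, atol=0.05)

    def test_consistency_at_large_n(self, rng):
        n = 100_000
        x = rng.standard_normal(n)
        p = 1 / (1 + np.exp(-x))  # true beta = (0, 1)
        y = (rng.random(n) < p).astype(int)
        fit = fit_bayes_logistic(x[:, None], y)
        se = np.sqrt(np.diag(fit.cov_hat))
        assert np.all(np.abs(fit.beta_hat - np.array([0.0, 1.0])) < 3 * se)

    def test_augmentation_tames_separated_data(self, rng):
        x = np.linspace(-2, 2, 40)
        y = (x > 0).astype(int)  # perfectly separated
        Xa, ya, wa = augment_observations(x[:, None], x[:, None], y)
        fit = fit_bayes_logistic(Xa, ya, weights=wa)
        assert fit.converged
        assert abs(fit.beta_hat[1]) < 20

    def test_augmentation_weights_total_p_plus_one(self, rng):
        X = rng.standard_normal((100, 2))
        y = rng.integers(0, 2, 60)
        _, _, w = augment_observations(X, X[:60], y)
        assert w[:60].sum() == 60
        assert w[60:].sum() == pytest.approx(3.0)  # p + 1 with p = 2


class TestDrawBeta:
    def test_degenerate_posterior_returns_mean_exactly(self, rng):
        fit = LogisticFit(
            beta_hat=np.array([0.2, -1.3]), cov_hat=np.zeros((2, 2)),
            converged=True, n_obs=10,
        )
        np.testing.assert_array_equal(draw_beta(fit, rng), fit.beta_hat)

    def test_draw_moments_match_posterior(self, rng):
        cov = np.array([[0.5, 0.2], [0.2, 0.4]])
        fit = LogisticFit(
            beta_hat=np.array([1.0, -2.0]), cov_hat=cov, converged=True, n_obs=10
        )
        draws = np.array([draw_beta(fit, rng) for _ in range(50_000)])
        np.testing.assert_allclose(draws.mean(axis=0), fit.beta_hat, atol=0.02)
        np.testing.assert_allclose(np.cov(draws.T), cov, atol=0.02)


class TestImputation:
    def test_imputed_fraction_tracks_probability(self, restricted_half, rng):
        # intercept-only log-odds of .8/.2 => imputed ones tend to 80%
        beta = np.array([np.log(4.0), 0.0])
        miss = ~restricted_half.selected
        fractions = [
            impute_once(restricted_half, beta, rng)[miss].mean() for _ in range(200)
        ]
        assert np.mean(fractions) == pytest.approx(0.80, abs=0.01)

    def test_null_coefficients_give_fair_coin(self, restricted_half, rng):
        miss = ~restricted_half.selected
        fractions = [
            impute_once(restricted_half, np.zeros(2), rng)[miss].mean()
            for _ in range(200)
        ]
        assert np.mean(fractions) == pytest.approx(0.5, abs=0.02)

    def test_saturated_probabilities_are_deterministic(self, restricted_half, rng):
        miss = ~restricted_half.selected
        y = impute_once(restricted_half, np.array([1000.0, 0.0]), rng)
        assert (y[miss] == 1).all()

    def test_observed_values_never_altered(self, restricted_half, rng):
        sel = restricted_half.selected
        for y in multiple_impute(restricted_half, m=10, rng=rng):
            np.testing.assert_array_equal(y[sel], restricted_half.observed_y())

    def test_no_missing_values_is_identity(self, drr_natural_dataset, rng):
        r = apply_selection(drr_natural_dataset, 1.0)
        completed = multiple_impute(r, m=20, rng=rng)
        assert len(completed) == 20
        for y in completed:
            np.testing.assert_array_equal(y, drr_natural_dataset.y)

    def test_same_seed_gives_identical_imputations(self, restricted_half):
        a = multiple_impute(restricted_half, m=5, rng=np.random.default_rng(3))
        b = multiple_impute(restricted_half, m=5, rng=np.random.default_rng(3))
        for ya, yb in zip(a, b):
            np.testing.assert_array_equal(ya, yb)


class TestPooling:
    def test_pooled_value_is_arithmetic_mean(self, rng):
        x = rng.standard_normal(30)
        ys = [rng.integers(0, 2, 30) for _ in range(3)]
        for y in ys:
            y[:2] = [0, 1]  # keep both categories present
        pooled = pool_estimates(x, ys, "natural")
        per = [point_biserial(x, y).value for y in ys]
        assert pooled.r_pb == pytest.approx(np.mean(per), abs=1e-12)
        assert pooled.br == pytest.approx(np.mean([y.mean() for y in ys]), abs=1e-12)

    def test_full_selection_pooled_equals_sample_statistics(
        self, drr_natural_dataset, rng
    ):
        r = apply_selection(drr_natural_dataset, 1.0)
        pooled = mice_estimate(r, m=20, rng=rng)
        assert pooled.r_pb == point_biserial(r.x, drr_natural_dataset.y).value
        assert pooled.br == drr_natural_dataset.y.mean()

    def test_artificial_kind_pools_biserial(self, drr_artificial_dataset, rng):
        r = apply_selection(drr_artificial_dataset, 0.5)
        pooled = mice_estimate(r, m=10, rng=rng)
        assert pooled.r_b is not None
        assert abs(pooled.r_b) >= abs(pooled.r_pb)

    def test_more_imputations_do_not_hurt_precision(self, drr_natural_dataset):
        # pooled-estimate variance shrinks as m grows (law of large numbers
        # on the imputation noise); compare spread of repeated pooled
        # estimates at m=2 vs m=30 on one restricted sample
        r = apply_selection(drr_natural_dataset, 0.4)
        rng = np.random.default_rng(5)
        small = [mice_estimate(r, m=2, rng=rng).r_pb for _ in range(40)]
        large = [mice_estimate(r, m=30, rng=rng).r_pb for _ in range(40)]
        assert np.var(large) < np.var(small)
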