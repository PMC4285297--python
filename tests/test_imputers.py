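import numpy as np
import pytest
from scipy import stats

from twofoldmi import imputers
from twofoldmi.imputers import (
    ImputerError,
    SeparationError,
    impute_binary,
    impute_categorical,
    impute_continuous,
    initialize_missing,
)
from twofoldmi.panel import CATEGORICAL, VariableSpec

from conftest import continuous_spec, make_panel


def oracle_normal_posterior_predictive(y_obs, X_obs, X_mis, rng, n_draws=2000):
    """Independent posterior-predictive sampler for the normal linear
    model (conjugate, flat prior): returns draws of the missing rows,
    shape (n_draws, n_mis).  Written against the textbook formulas, not
    the implementation under test."""
    Xo = np.column_stack([np.ones(len(X_obs)), X_obs])
    Xm = np.column_stack([np.ones(len(X_mis)), X_mis])
    beta_hat, *_ = np.linalg.lstsq(Xo, y_obs, rcond=None)
    resid = y_obs - Xo @ beta_hat
    nu = Xo.shape[0] - Xo.shape[1]
    rss = resid @ resid
    xtx_inv = np.linalg.inv(Xo.T @ Xo)
    chol = np.linalg.cholesky(xtx_inv)
    out = np.empty((n_draws, len(X_mis)))
    for d in range(n_draws):
        s2 = rss / rng.chisquare(nu)
        beta = beta_hat + np.sqrt(s2) * chol @ rng.standard_normal(len(beta_hat))
        out[d] = Xm @ beta + np.sqrt(s2) * rng.standard_normal(len(X_mis))
    return out


class TestImputeContinuous:
    def test_fully_observed_is_noop(self, rng):
        y = rng.standard_normal(50)
        X = rng.standard_normal((50, 2))
        res = impute_continuous(y, X, np.zeros(50, bool), rng)
        assert res.n_imputed == 0

    def test_collinear_predictor_dropped_and_logged(self, rng):
        n = 60
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])  # col 0 = intercept copy
        y = rng.standard_normal(n)
        mis = np.zeros(n, bool)
        mis[:5] = True
        res = impute_continuous(y, X, mis, rng)
        assert res.n_imputed == 5
        assert len(res.dropped) == 1

    def test_deterministic_mode_reproduces_least_squares(self, rng):
        n = 200
        X = rng.standard_normal((n, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.standard_normal(n)
        mis = np.zeros(n, bool)
        mis[:20] = True
        res = impute_continuous(y, X, mis, rng, deterministic=True)
        Xo = np.column_stack([np.ones(n - 20), X[20:]])
        beta, *_ = np.linalg.lstsq(Xo, y[20:], rcond=None)
        expect = np.column_stack([np.ones(20), X[:20]]) @ beta
        np.testing.assert_allclose(res.values, expect, rtol=1e-8)

    def test_too_few_rows_errors(self, rng):
        y = np.array([1.0, 2.0, np.nan])
        X = np.random.default_rng(0).standard_normal((3, 2))
        with pytest.raises(ImputerError, match="too few"):
            impute_continuous(y, X, np.array([False, False, True]), rng)

    def test_matches_posterior_predictive_oracle(self, rng):
        # y = 2x + e: mean of imputations tracks 2 * mean(x at missing rows)
        n_obs, n_mis = 10_000, 1000
        x = rng.standard_normal(n_obs + n_mis)
        y = 2.0 * x + rng.standard_normal(n_obs + n_mis)
        mis = np.zeros(n_obs + n_mis, bool)
        mis[:n_mis] = True
        oracle = oracle_normal_posterior_predictive(
            y[~mis], x[~mis, None], x[mis, None], np.random.default_rng(77), n_draws=400
        )
        oracle_mean = oracle.mean()
        oracle_sd = oracle.mean(axis=1).std()
        draws = np.array([
            impute_continuous(y, x[:, None], mis, np.random.default_rng(1000 + i)).values.mean()
            for i in range(40)
        ])
        # both should estimate E[2 * mean(x_mis)]; compare at MC precision
        assert abs(draws.mean() - oracle_mean) < 4 * oracle_sd / np.sqrt(40) + 4 * oracle_sd / np.sqrt(400)
        assert abs(draws.mean() - 2.0 * x[mis].mean()) < 5 * oracle_sd


class TestImputeBinary:
    def test_constant_observed_response_signalled(self, rng):
        y = np.ones(30)
        mis = np.zeros(30, bool)
        mis[:3] = True
        with pytest.raises(SeparationError):
            impute_binary(y, np.empty((30, 0)), mis, rng)

    def test_no_missing_is_noop(self, rng):
        y = (rng.random(40) < 0.5).astype(float)
        res = impute_binary(y, rng.standard_normal((40, 1)), np.zeros(40, bool), rng)
        assert res.n_imputed == 0

    def test_null_model_prevalence_matches_binomial_oracle(self):
        # y independent of X with P(1) = 0.5: imputed prevalence ~ 0.5
        n, n_mis = 4000, 1500
        rng = np.random.default_rng(3)
        y = (rng.random(n) < 0.5).astype(float)
        X = rng.standard_normal((n, 2))
        mis = np.zeros(n, bool)
        mis[:n_mis] = True
        vals = np.concatenate([
            impute_binary(y, X, mis, np.random.default_rng(50 + i)).values
            for i in range(4)
        ])
        se = 0.5 / np.sqrt(len(vals))
        assert abs(vals.mean() - 0.5) < 6 * se


class TestImputeCategorical:
    def test_balanced_levels_match_multinomial_oracle(self):
        n, n_mis = 6000, 2000
        rng = np.random.default_rng(9)
        y = rng.integers(0, 3, n).astype(float)
        X = rng.standard_normal((n, 2))
        mis = np.zeros(n, bool)
        mis[:n_mis] = True
        res = impute_categorical(y, X, mis, np.random.default_rng(10), 3)
        freqs = np.bincount(res.values.astype(int), minlength=3) / n_mis
        se = np.sqrt((1 / 3) * (2 / 3) / n_mis)
        for f in freqs:
            assert abs(f - 1 / 3) < 6 * se

    def test_two_observed_levels_reduce_to_binary_support(self, rng):
        n = 500
        y = np.where(np.arange(n) % 2 == 0, 0.0, 2.0)  # level 1 never observed
        X = rng.standard_normal((n, 1))
        mis = np.zeros(n, bool)
        mis[:100] = True
        res = impute_categorical(y, X, mis, rng, 3)
        assert set(np.unique(res.values)) <= {0, 2}

    def test_unobserved_level_gets_zero_probability(self, rng):
        n = 3000
        y = np.where(np.random.default_rng(4).random(n) < 0.5, 0.0, 1.0)
        X = np.random.default_rng(5).standard_normal((n, 1))
        mis = np.zeros(n, bool)
        mis[:500] = True
        res = impute_categorical(y, X, mis, rng, n_levels=4)
        assert set(np.unique(res.values)) <= {0, 1}

    def test_no_missing_is_noop(self, rng):
        y = rng.integers(0, 3, 50).astype(float)
        res = impute_categorical(y, rng.standard_normal((50, 1)), np.zeros(50, bool), rng, 3)
        assert res.n_imputed == 0


class TestInitializeMissing:
    def test_degenerate_marginal_fills_constant(self, rng):
        spec = continuous_spec("v")
        panel = make_panel([spec], 6, 1)
        where = np.zeros((6, 1), dtype=bool)
        where[:3, 0] = True
        panel.set_cells("v", where, np.array([1.0, 1.0, 1.0]))
        out = initialize_missing(panel, rng)
        assert np.all(out.values("v") == 1.0)

    def test_fully_observed_identity(self, rng):
        panel = make_panel([continuous_spec("v")], 10, 2, fill="complete")
        out = initialize_missing(panel, rng)
        assert out == panel

    def test_empty_block_errors(self, rng):
        panel = make_panel([continuous_spec("v")], 4, 2)
        with pytest.raises(Exception, match="no observed values"):
            initialize_missing(panel, rng)

    def test_initial_marginal_matches_observed_marginal(self):
        # resampling oracle: imputed marginal ~ observed marginal (KS)
        rng = np.random.default_rng(11)
        panel = make_panel([continuous_spec("v")], 4000, 1)
        obs = rng.random(4000) < 0.5
        panel.set_cells("v", obs[:, None], rng.standard_normal(int(obs.sum())))
        out = initialize_missing(panel, np.random.default_rng(12))
        observed_vals = panel.values("v")[panel.mask("v")]
        imputed_vals = out.values("v")[~panel.mask("v")]
        assert stats.ks_2samp(observed_vals, imputed_vals).pvalue > 1e-4

    def test_observed_cells_untouched_and_reproducible(self, rng):
        panel = make_panel([continuous_spec("v")], 200, 3)
        obs = np.random.default_rng(1).random((200, 3)) < 0.4
        panel.set_cells("v", obs, np.random.default_rng(2).standard_normal(int(obs.sum())))
        a = initialize_missing(panel, np.random.default_rng(99))
        b = initialize_missing(panel, np.random.default_rng(99))
        assert a == b
        assert np.array_equal(a.values("v")[obs], panel.values("v")[obs])
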