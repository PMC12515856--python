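"""Cox partial-likelihood fitting against closed forms and oracles."""

import numpy as np
import pytest

from cpmkit.cox import cox_partial_log_likelihood, fit_cox, predict_cox_linear_predictor


class TestPartialLogLikelihood:
    def test_null_beta_three_events(self):
        # all events, distinct times: risk sets of size 3, 2, 1
        X = np.array([[0.5], [-0.2], [1.0]])
        ll = cox_partial_log_likelihood(np.zeros(1), X, [1.0, 2.0, 3.0], [1, 1, 1])
        assert ll == pytest.approx(-np.log(6.0), abs=1e-12)

    def test_null_beta_closed_form_untied(self, rng):
        n = 25
        time = rng.exponential(size=n) + 0.01
        status = (rng.random(n) < 0.6).astype(int)
        status[0] = 1
        X = rng.normal(size=(n, 3))
        risk_sizes = [np.sum(time >= time[k]) for k in range(n) if status[k] == 1]
        ll = cox_partial_log_likelihood(np.zeros(3), X, time, status)
        assert ll == pytest.approx(-np.sum(np.log(risk_sizes)), abs=1e-10)

    def test_censoring_drops_factor_keeps_risk(self):
        # times 1 < 2 < 3, middle subject censored: events contribute risk
        # sets {1,2,3} and {3}; the censored subject appears only as risk
        x = np.array([0.3, -0.4, 0.8])
        time = np.array([1.0, 2.0, 3.0])
        status = np.array([1, 0, 1])
        beta = 0.7
        hand = (
            beta * x[0] - np.log(np.exp(beta * x).sum())
            + beta * x[2] - np.log(np.exp(beta * x[2]))
        )
        ll = cox_partial_log_likelihood(np.array([beta]), x[:, None], time, status)
        assert ll == pytest.approx(hand, abs=1e-12)

    def test_column_shift_invariance_at_zero_coordinate(self, rng):
        n = 15
        X = rng.normal(size=(n, 2))
        time = rng.exponential(size=n) + 0.1
        status = np.ones(n, int)
        beta = np.array([0.8, 0.0])
        X_shift = X.copy()
        X_shift[:, 1] += 5.0
        ll1 = cox_partial_log_likelihood(beta, X, time, status)
        ll2 = cox_partial_log_likelihood(beta, X_shift, time, status)
        assert ll1 == pytest.approx(ll2, abs=1e-12)

    def test_monotone_time_transform_invariance(self, rng):
        n = 20
        X = rng.normal(size=(n, 2))
        time = rng.exponential(size=n) + 0.1
        status = (rng.random(n) < 0.7).astype(int)
        status[:2] = 1
        beta = rng.normal(size=2)
        ll = cox_partial_log_likelihood(beta, X, time, status)
        for transform in (np.exp, lambda t: t**3, lambda t: np.log1p(t) + 1):
            ll_t = cox_partial_log_likelihood(beta, X, transform(time), status)
            assert ll_t == pytest.approx(ll, abs=1e-10)


class TestFit:
    def test_single_covariate_matches_grid_oracle(self, rng):
        n = 40
        x = rng.normal(size=n)
        time = rng.exponential(1 / np.exp(0.9 * x))
        status = np.ones(n, int)
        fit = fit_cox(x[:, None], time, status)
        grid = np.arange(-5.0, 5.0, 1e-4)
        lls = [cox_partial_log_likelihood(np.array([b]), x[:, None], time, status) for b in grid]
        assert fit.beta[0] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-3)

    def test_exchangeable_covariate_near_zero(self, rng):
        n = 60
        x = rng.normal(size=n)
        time = rng.exponential(size=n)  # independent of x
        fit = fit_cox(x[:, None], time, np.ones(n, int))
        assert abs(fit.beta[0]) < 0.35  # ~2 se at this n

    def test_scale_equivariance(self, rng):
        n = 50
        X = rng.normal(size=(n, 2))
        time = rng.exponential(1 / np.exp(0.5 * X[:, 0]))
        f1 = fit_cox(X, time, np.ones(n, int))
        X2 = X.copy()
        X2[:, 0] *= 2.0
        f2 = fit_cox(X2, time, np.ones(n, int))
        assert f2.beta[0] == pytest.approx(f1.beta[0] / 2.0, abs=1e-6)
        assert f2.beta[1] == pytest.approx(f1.beta[1], abs=1e-6)

    def test_matches_lifelines_untied(self, rng):
        import pandas as pd
        from lifelines import CoxPHFitter

        n = 60
        X = rng.normal(size=(n, 2))
        time = rng.exponential(2 / np.exp(0.6 * X[:, 0]), size=n)  # continuous ⇒ untied
        status = (rng.random(n) < 0.8).astype(int)
        fit = fit_cox(X, time, status)
        df = pd.DataFrame({"x0": X[:, 0], "x1": X[:, 1], "t": time, "s": status})
        cph = CoxPHFitter().fit(df, "t", "s")  # tie corrections coincide when untied
        np.testing.assert_allclose(fit.beta, cph.params_.values, atol=1e-4)

    def test_breslow_ties_match_direct_optimization(self, rng):
        from scipy.optimize import minimize

        n = 40
        X = rng.normal(size=(n, 2))
        time = np.ceil(rng.exponential(2 / np.exp(0.6 * X[:, 0]), size=n) * 4) / 4  # ties
        status = (rng.random(n) < 0.8).astype(int)
        status[:2] = 1

        def neg_breslow(beta):
            eta = X @ beta
            ll = 0.0
            for k in range(n):
                if status[k] != 1:
                    continue
                risk = time >= time[k]
                ll += eta[k] - np.log(np.exp(eta[risk]).sum())
            return -ll

        fit = fit_cox(X, time, status)
        oracle = minimize(neg_breslow, np.zeros(2), method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-12})
        np.testing.assert_allclose(fit.beta, oracle.x, atol=1e-4)

    def test_monotone_likelihood_warns(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        time = np.array([6.0, 5.0, 4.0, 3.0, 2.0, 1.0])  # perfectly reversed
        with pytest.warns(RuntimeWarning, match="monotone|separation"):
            fit = fit_cox(x[:, None], time, np.ones(6, int))
        assert not fit.converged

    def test_too_few_events(self, rng):
        with pytest.raises(ValueError, match="≥2 observed events"):
            fit_cox(rng.normal(size=(5, 1)), np.arange(1.0, 6.0), np.array([1, 0, 0, 0, 0]))


class TestPredict:
    def test_zero_beta_zero_predictors(self, rng):
        n = 30
        X = rng.normal(size=(n, 2))
        time = rng.exponential(size=n)
        fit = fit_cox(X, time, np.ones(n, int))
        zeroed = fit.__class__(np.zeros(2), fit.log_partial_likelihood, True, 1, n, fit.column_names)
        np.testing.assert_array_equal(predict_cox_linear_predictor(zeroed, X), np.zeros(n))

    def test_centering_shifts_by_constant(self, rng):
        n = 30
        X = rng.normal(size=(n, 2))
        time = rng.exponential(1 / np.exp(0.5 * X[:, 0]))
        fit = fit_cox(X, time, np.ones(n, int))
        lp = predict_cox_linear_predictor(fit, X)
        lp_c = predict_cox_linear_predictor(fit, X - X.mean(axis=0))
        np.testing.assert_allclose(lp - lp_c, np.full(n, X.mean(axis=0) @ fit.beta), atol=1e-10)

    def test_linear_predictor_ranks_drive_concordance(self, rng):
        from cpmkit.evaluation import c_index

        n = 120
        x = rng.normal(size=n)
        time = rng.exponential(1 / np.exp(1.2 * x))
        fit = fit_cox(x[:, None], time, np.ones(n, int))
        lp = predict_cox_linear_predictor(fit, x[:, None])
        ci = c_index(lp, time, np.ones(n, int))
        assert ci > 0.7  # strong planted effect ⇒ well above chance
        # monotone transform of lp leaves the c-index unchanged
        assert c_index(np.tanh(lp), time, np.ones(n, int)) == pytest.approx(ci)
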