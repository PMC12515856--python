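"""Penalized fits: closed forms, penalty-exemption contract, λ selection."""

import numpy as np
import pytest

from cpmkit.core import CovariateTable, Outcome
from cpmkit.design import assemble_design
from cpmkit.glm import fit_glm
from cpmkit.cox import fit_cox
from cpmkit.penalized import (
    PenaltySpec,
    fit_penalized,
    lambda_path,
    select_lambda,
)
from conftest import centered_unit_design


class TestAgainstClosedForms:
    def test_zero_lambda_matches_unpenalized(self, gaussian_problem):
        design, outcome = gaussian_problem
        pf = fit_penalized(design, outcome, penalty=PenaltySpec("lasso"), lambda_value=0.0)
        g = fit_glm(design, outcome)
        np.testing.assert_allclose(pf.beta, g.beta[1:], atol=1e-6)
        assert pf.intercept == pytest.approx(g.beta[0], abs=1e-6)

    def test_ridge_matches_closed_form(self, gaussian_problem):
        design, outcome = gaussian_problem
        n, p = design.X_star.shape
        lam = 0.6
        pf = fit_penalized(design, outcome, penalty=PenaltySpec("ridge"), lambda_value=lam)
        X, y = design.X_star, outcome.y
        I_A = np.diag(design.penalty_mask)
        oracle = np.linalg.solve(X.T @ X / n + 2 * lam * I_A, X.T @ y / n)
        np.testing.assert_allclose(pf.beta, oracle, atol=1e-6)

    def test_lasso_soft_threshold_on_orthonormal_block(self, rng):
        # centered columns with XᵀX = nI and unit population sd: the lasso
        # solution decouples into coordinate-wise soft thresholding
        n, K = 32, 6
        raw = rng.normal(size=(n, K))
        raw -= raw.mean(axis=0)
        Q, _ = np.linalg.qr(raw)
        X = Q * np.sqrt(n)
        y = rng.normal(size=n)
        y -= y.mean()
        design = assemble_design(X)
        lam = 0.05
        pf = fit_penalized(design, Outcome.continuous(y), penalty=PenaltySpec("lasso"), lambda_value=lam)
        rho = X.T @ y / n
        oracle = np.sign(rho) * np.maximum(np.abs(rho) - lam, 0.0)
        np.testing.assert_allclose(pf.beta, oracle, atol=1e-8)

    def test_matches_sklearn_elasticnet(self, rng):
        from sklearn.linear_model import ElasticNet

        design, A, _ = centered_unit_design(n=70, K=8, J=0, rng=rng)
        y = A @ [0.8, -0.5, 0, 0, 0.3, 0, 0, 0] + rng.normal(0, 0.4, 70)
        lam = 0.07
        pf = fit_penalized(
            design, Outcome.continuous(y), penalty=PenaltySpec("lasso"), lambda_value=lam
        )
        sk = ElasticNet(alpha=lam, l1_ratio=1.0, fit_intercept=True, tol=1e-10, max_iter=100000)
        sk.fit(A, y)
        np.testing.assert_allclose(pf.beta, sk.coef_, atol=1e-5)


class TestMixingParameter:
    """The mixing weight α multiplies the squared-L2 term (α = λ₂/(λ₁+λ₂)),
    so the α = 0 endpoint is the pure lasso and α = 1 the pure ridge."""

    @pytest.mark.parametrize("lam", [0.05, 0.4])
    def test_alpha_endpoints_reproduce_pure_penalties(self, gaussian_problem, lam):
        design, outcome = gaussian_problem
        lasso = fit_penalized(design, outcome, penalty=PenaltySpec("lasso"), lambda_value=lam)
        en0 = fit_penalized(design, outcome, penalty=PenaltySpec("EN", alpha=0.0), lambda_value=lam)
        ridge = fit_penalized(design, outcome, penalty=PenaltySpec("ridge"), lambda_value=lam)
        en1 = fit_penalized(design, outcome, penalty=PenaltySpec("EN", alpha=1.0), lambda_value=lam)
        np.testing.assert_allclose(en0.beta, lasso.beta, atol=1e-8)
        np.testing.assert_allclose(en1.beta, ridge.beta, atol=1e-8)

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError, match="alpha"):
            PenaltySpec("EN", alpha=1.5)

    def test_negative_lambda(self, gaussian_problem):
        design, outcome = gaussian_problem
        with pytest.raises(ValueError, match="nonnegative"):
            fit_penalized(design, outcome, lambda_value=-1.0)


class TestPenaltyExemption:
    def test_huge_lambda_zeroes_edges_keeps_covariate_fit(self, rng):
        design, A, C = centered_unit_design(n=60, K=6, J=2, rng=rng)
        y = A @ [0.5, 0, 0, -0.3, 0, 0] + C @ [1.2, -0.7] + rng.normal(0, 0.3, 60)
        outcome = Outcome.continuous(y)
        for ptype in ("lasso", "EN"):
            pf = fit_penalized(design, outcome, penalty=PenaltySpec(ptype, alpha=0.5), lambda_value=1e6)
            np.testing.assert_array_equal(pf.beta[:6], np.zeros(6))
            assert len(pf.active_edges) == 0
            cov_only = fit_glm(
                assemble_design(None, CovariateTable(C, ("c0", "c1"))), outcome
            )
            np.testing.assert_allclose(pf.beta[6:], cov_only.beta[1:], atol=1e-6)
            assert pf.intercept == pytest.approx(cov_only.beta[0], abs=1e-6)

    def test_covariates_never_zeroed_binomial(self, rng):
        design, A, C = centered_unit_design(n=80, K=5, J=2, rng=rng)
        p = 1 / (1 + np.exp(-(A[:, 0] + C @ [1.0, -0.8])))
        y = (rng.random(80) < p).astype(int).astype(str)
        outcome = Outcome.binary(y, levels=("0", "1"))
        pf = fit_penalized(design, outcome, penalty=PenaltySpec("lasso"), lambda_value=1e6)
        np.testing.assert_array_equal(pf.beta[:5], np.zeros(5))
        assert np.all(np.abs(pf.beta[5:]) > 1e-4)

    def test_ridge_keeps_all_edges_nonzero(self, gaussian_problem):
        design, outcome = gaussian_problem
        pf = fit_penalized(design, outcome, penalty=PenaltySpec("ridge"), lambda_value=0.5)
        assert np.all(pf.beta[design.edge_block_cols] != 0)

    def test_lasso_active_set_monotone_along_path(self, rng):
        design, A, _ = centered_unit_design(n=50, K=10, J=2, rng=rng)
        y = A @ ([0.6, -0.5, 0.4, 0, 0, 0, 0, 0, 0, 0]) + rng.normal(0, 0.5, 50)
        outcome = Outcome.continuous(y)
        path = lambda_path(design, outcome, penalty=PenaltySpec("lasso"), n_lambda=25)
        sizes = [
            len(fit_penalized(design, outcome, penalty=PenaltySpec("lasso"), lambda_value=lam).active_edges)
            for lam in path  # decreasing λ
        ]
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))
        assert sizes[0] == 0  # top of the path zeroes every edge


class TestFamilies:
    def test_multinomial_zero_lambda_matches_unpenalized(self, rng):
        design, A, _ = centered_unit_design(n=90, K=3, J=1, rng=rng)
        s = A[:, 0] - 0.5 * A[:, 1]
        P = np.exp(np.column_stack([0 * s, s, -s]))
        P /= P.sum(axis=1, keepdims=True)
        codes = np.array([rng.choice(3, p=p) for p in P])
        out = Outcome.categorical(np.asarray(("a", "b", "c"))[codes], levels=("a", "b", "c"))
        pf = fit_penalized(design, out, penalty=PenaltySpec("lasso"), lambda_value=0.0)
        g = fit_glm(design, out)
        np.testing.assert_allclose(pf.beta, g.beta[:, 1:], atol=1e-4)

    def test_cox_zero_lambda_matches_newton(self, rng):
        design, A, C = centered_unit_design(n=70, K=3, J=1, rng=rng)
        time = rng.exponential(1 / np.exp(0.6 * A[:, 0] - 0.4 * C[:, 0]))
        out = Outcome.survival(time, np.ones(70, int))
        pf = fit_penalized(design, out, penalty=PenaltySpec("lasso"), lambda_value=0.0)
        nf = fit_cox(design.X_star, time, np.ones(70, int))
        np.testing.assert_allclose(pf.beta, nf.beta, atol=1e-5)

    def test_cox_huge_lambda_keeps_covariate_only_fit(self, rng):
        design, A, C = centered_unit_design(n=70, K=3, J=1, rng=rng)
        time = rng.exponential(1 / np.exp(0.8 * C[:, 0]))
        out = Outcome.survival(time, np.ones(70, int))
        pf = fit_penalized(design, out, penalty=PenaltySpec("lasso"), lambda_value=1e6)
        np.testing.assert_array_equal(pf.beta[:3], np.zeros(3))
        cov_fit = fit_cox(C, time, np.ones(70, int))
        np.testing.assert_allclose(pf.beta[3:], cov_fit.beta, atol=1e-5)


class TestLambdaSelection:
    def test_noise_edges_strong_covariate_prefers_heavy_shrinkage(self, rng):
        design, A, C = centered_unit_design(n=100, K=15, J=1, rng=rng)
        y = C[:, 0] * 2.0 + rng.normal(0, 0.5, 100)  # edges are pure noise
        outcome = Outcome.continuous(y)
        lam, lams, dev = select_lambda(design, outcome, penalty=PenaltySpec("lasso"), inner_folds=5, seed=3)
        assert lam >= np.median(lams)  # chosen near the top of the path
        pf = fit_penalized(design, outcome, penalty=PenaltySpec("lasso"), lambda_value=lam)
        assert len(pf.active_edges) <= 3

    def test_deterministic_given_seed(self, gaussian_problem):
        design, outcome = gaussian_problem
        r1 = select_lambda(design, outcome, inner_folds=4, seed=11)
        r2 = select_lambda(design, outcome, inner_folds=4, seed=11)
        assert r1[0] == r2[0]
        np.testing.assert_array_equal(r1[2], r2[2])

    def test_path_invariant_under_row_duplication(self, gaussian_problem):
        design, outcome = gaussian_problem
        path1 = lambda_path(design, outcome, penalty=PenaltySpec("lasso"))
        dup_design = assemble_design(
            np.vstack([design.X_star[:, design.edge_block_cols]] * 2),
            CovariateTable(
                np.vstack([design.X_star[:, design.covariate_cols]] * 2),
                design.column_names[design.K :],
            ),
        )
        dup_outcome = Outcome.continuous(np.concatenate([outcome.y, outcome.y]))
        path2 = lambda_path(dup_design, dup_outcome, penalty=PenaltySpec("lasso"))
        np.testing.assert_allclose(path1[0], path2[0], rtol=1e-10)

    def test_path_is_strictly_decreasing(self, gaussian_problem):
        design, outcome = gaussian_problem
        path = lambda_path(design, outcome)
        assert np.all(np.diff(path) < 0)
        assert len(path) == 100

    def test_inner_folds_floor(self, gaussian_problem):
        design, outcome = gaussian_problem
        with pytest.raises(ValueError, match="inner_folds"):
            select_lambda(design, outcome, inner_folds=1)
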