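"""Edge-wise marginal screening against brute-force and grid oracles."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from cpmkit.core import EdgeIndex, Outcome
from cpmkit.screening import (
    encode_outcome_for_screening,
    screen_edges_correlation,
    screen_edges_cox,
)


@pytest.fixture
def toy_table(rng):
    """n=5, E=4: one strong positive, one strong negative, two noise edges."""
    y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    edges = np.column_stack(
        [
            y + rng.normal(0, 0.05, 5),
            -2 * y + rng.normal(0, 0.05, 5),
            rng.normal(size=5),
            rng.normal(size=5),
        ]
    )
    return edges, y


class TestCorrelationScreening:
    def test_matches_per_edge_brute_force(self, toy_table):
        edges, y = toy_table
        res = screen_edges_correlation(edges, y, "pearson", thresh=0.05)
        for k in range(edges.shape[1]):
            r_k, p_k = stats.pearsonr(edges[:, k], y)
            assert res.stat[k] == pytest.approx(r_k, abs=1e-12)
            assert res.p[k] == pytest.approx(p_k, abs=1e-12)
        expect_sel = {k for k in range(4) if stats.pearsonr(edges[:, k], y)[1] < 0.05}
        assert set(res.selected.tolist()) == expect_sel

    def test_spearman_matches_scipy(self, rng):
        edges = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        res = screen_edges_correlation(edges, y, "spearman", thresh=0.5)
        for k in range(6):
            rho, _ = stats.spearmanr(edges[:, k], y)
            assert res.stat[k] == pytest.approx(rho, abs=1e-10)

    def test_perfect_edge_in_positive_set(self, rng):
        y = np.arange(6, dtype=float)
        edges = np.column_stack([y, rng.normal(size=6)])
        res = screen_edges_correlation(edges, y, thresh=0.05)
        assert res.stat[0] == pytest.approx(1.0)
        assert res.p[0] == pytest.approx(0.0, abs=1e-12)
        assert 0 in res.positive_edges

    def test_thresh_one_selects_all_nondegenerate(self, rng):
        edges = rng.normal(size=(10, 8))
        edges[:, 3] = 7.0  # degenerate
        res = screen_edges_correlation(edges, rng.normal(size=10), thresh=1.0)
        assert set(res.selected.tolist()) == set(range(8)) - {3}
        assert res.p[3] == 1.0

    @pytest.mark.parametrize("t1,t2", [(0.001, 0.01), (0.01, 0.2), (0.2, 1.0)])
    def test_selection_monotone_in_thresh(self, rng, t1, t2):
        edges = rng.normal(size=(25, 30))
        y = edges[:, 0] * 0.5 + rng.normal(size=25)
        s1 = screen_edges_correlation(edges, y, thresh=t1)
        s2 = screen_edges_correlation(edges, y, thresh=t2)
        assert set(s1.selected.tolist()) <= set(s2.selected.tolist())
        assert np.all(s2.p[s2.selected] < t2)

    def test_pearson_p_equals_t_transform(self, rng):
        edges = rng.normal(size=(15, 5))
        y = rng.normal(size=15)
        res = screen_edges_correlation(edges, y, thresh=0.5)
        n = 15
        t = res.stat * np.sqrt((n - 2) / (1 - res.stat**2))
        np.testing.assert_allclose(res.p, 2 * stats.t.sf(np.abs(t), n - 2), atol=1e-14)

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            screen_edges_correlation(rng.normal(size=(8, 3)), np.ones(8))
        with pytest.raises(ValueError, match="at least 4"):
            screen_edges_correlation(rng.normal(size=(3, 2)), np.arange(3.0))

    def test_export_uses_one_based_nodes(self, rng):
        edges = rng.normal(size=(10, 3))
        res = screen_edges_correlation(edges, rng.normal(size=10), thresh=1.0)
        frame = res.to_frame(EdgeIndex(3))
        assert list(frame["edge_i"]) == [1, 1, 2]
        assert list(frame["edge_j"]) == [2, 3, 3]


class TestOutcomeEncoding:
    def test_binary_level_order(self):
        out = Outcome.binary(["control", "case", "case"], levels=("control", "case"))
        np.testing.assert_array_equal(encode_outcome_for_screening(out), [0, 1, 1])

    def test_categorical_codes(self):
        levels = tuple(f"b{i}" for i in range(5))
        out = Outcome.categorical(np.array(levels), levels=levels)
        np.testing.assert_array_equal(encode_outcome_for_screening(out), range(5))

    def test_continuous_identity_and_survival_error(self):
        y = np.array([0.5, 1.5, -2.0])
        np.testing.assert_array_equal(
            encode_outcome_for_screening(Outcome.continuous(y)), y
        )
        with pytest.raises(ValueError, match="screen_edges_cox"):
            encode_outcome_for_screening(Outcome.survival([1, 2, 3], [1, 1, 0]))


def _hand_partial_loglik(beta, x, time, status):
    """Direct enumeration of the partial likelihood for a tiny sample."""
    ll = 0.0
    for k in range(len(time)):
        if status[k] != 1:
            continue
        risk = [j for j in range(len(time)) if time[j] >= time[k]]
        ll += beta * x[k] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


class TestCoxScreening:
    def test_constant_edge_never_selected(self, rng):
        edges = np.column_stack([np.full(8, 3.0), rng.normal(size=8)])
        res = screen_edges_cox(edges, rng.exponential(size=8) + 0.1, np.ones(8, int), 1.0)
        assert res.p[0] == 1.0
        assert 0 not in res.selected

    def test_prognostic_edge_selected_with_positive_sign(self, rng):
        n = 80
        x = rng.normal(size=n)
        time = rng.exponential(1 / np.exp(1.5 * x))
        edges = np.column_stack([2.0 * x, rng.normal(size=n)])
        res = screen_edges_cox(edges, time, np.ones(n, int), thresh=1e-4)
        assert 0 in res.positive_edges
        assert res.stat[0] > 0

    def test_wald_matches_golden_section_oracle(self):
        # event order not monotone in x, so the MLE is finite and interior
        x = np.array([0.0, 1.0, 2.0])
        time = np.array([2.0, 1.0, 3.0])
        status = np.array([1, 1, 1])
        res = screen_edges_cox(x[:, None], time, status, thresh=1.0)
        opt = minimize_scalar(
            lambda b: -_hand_partial_loglik(b, x, time, status),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-12},
        )
        beta_hat = opt.x
        # observed information by direct enumeration of the risk-set moments
        info = 0.0
        for k in range(len(time)):
            if status[k] != 1:
                continue
            risk = [j for j in range(len(time)) if time[j] >= time[k]]
            w = np.exp(beta_hat * x[risk])
            m1 = (w * x[risk]).sum() / w.sum()
            m2 = (w * x[risk] ** 2).sum() / w.sum()
            info += m2 - m1**2
        p_oracle = 2 * stats.norm.sf(abs(beta_hat) * np.sqrt(info))
        assert res.stat[0] == pytest.approx(beta_hat, abs=1e-5)
        assert res.p[0] == pytest.approx(p_oracle, abs=1e-6)

    def test_matches_lifelines_univariate(self, rng):
        import pandas as pd
        from lifelines import CoxPHFitter

        n = 50
        x = rng.normal(size=n)
        time = rng.exponential(1 / np.exp(0.8 * x))
        status = (rng.random(n) < 0.7).astype(int)
        res = screen_edges_cox(x[:, None], time, status, thresh=1.0)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"x": x, "t": time, "s": status}), "t", "s"
        )
        assert res.stat[0] == pytest.approx(cph.params_["x"], abs=1e-4)
        assert res.p[0] == pytest.approx(cph.summary.loc["x", "p"], abs=1e-4)

    def test_no_events_error(self, rng):
        with pytest.raises(ValueError, match="events"):
            screen_edges_cox(rng.normal(size=(6, 2)), np.arange(1.0, 7.0), np.zeros(6, int))
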