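"""Logistic fitting, ROC construction and panel combination search."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circmir import (evaluate_panel, fit_logistic, roc_curve,
                     search_combinations)


def loglik_grid_oracle(x, y, intercepts, slopes):
    """Brute-force best log-likelihood over a coefficient lattice."""
    best = -np.inf
    for b0 in intercepts:
        for b1 in slopes:
            p = 1.0 / (1.0 + np.exp(-(b0 + b1 * x)))
            p = np.clip(p, 1e-12, 1 - 1e-12)
            ll = np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
            best = max(best, ll)
    return best


def make_nrq(values: np.ndarray, columns) -> pd.DataFrame:
    idx = [f"s{i}" for i in range(values.shape[0])]
    return pd.DataFrame(10.0 ** values, index=idx, columns=columns)


def make_labels(y) -> pd.Series:
    return pd.Series(np.asarray(y), index=[f"s{i}" for i in range(len(y))])


class TestFitLogistic:
    def test_intercept_only_balanced(self):
        X = np.zeros((8, 0))
        y = np.array([1, 0] * 4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_logistic(np.ones((8, 1)), y)  # constant predictor dropped
        assert m.dropped == ["x0"]
        assert m.coefficients[0] == pytest.approx(0.0, abs=1e-8)

    def test_loglik_beats_grid_oracle(self, logistic_8sample_fixture):
        x, y = logistic_8sample_fixture
        m = fit_logistic(x, y)
        assert m.converged
        oracle = loglik_grid_oracle(x.ravel(), y,
                                    np.linspace(-5, 5, 201),
                                    np.linspace(-10, 10, 401))
        assert m.log_likelihood >= oracle - 1e-3

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 2))
        y = (X[:, 0] + 0.5 * X[:, 1] + rng.normal(size=60) > 0).astype(int)
        m = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.allclose(m.coefficients, ref.params, atol=1e-6)
        assert m.log_likelihood == pytest.approx(ref.llf, abs=1e-6)

    def test_separation_detected(self):
        x = np.array([[0.0], [0.1], [0.2], [0.8], [0.9], [1.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.warns(UserWarning, match="separation"):
            m = fit_logistic(x, y)
        assert m.separation_detected

    def test_collinear_column_dropped(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=40)
        X = np.column_stack([a, 2 * a - 1])
        y = (a > 0).astype(int)
        y[:3] = 1 - y[:3]  # avoid separation
        with pytest.warns(UserWarning, match="collinear"):
            m = fit_logistic(X, y)
        assert len(m.mirna_ids) == 1 and len(m.dropped) == 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.arange(4.0).reshape(-1, 1), np.ones(4))


class TestRocCurve:
    def test_perfect_separation(self):
        roc = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auc == 1.0
        assert roc.operating_point[1:] == (1.0, 1.0)

    def test_three_quarters_fixture(self):
        roc = roc_curve([0.9, 0.3, 0.4, 0.1], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(0.75)

    def test_label_flip_complement(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        a1 = roc_curve(s, y).auc
        a2 = roc_curve(s, 1 - y).auc
        assert a1 + a2 == pytest.approx(1.0)

    def test_auc_equals_mann_whitney_u(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n1, n2 = rng.integers(3, 15, 2)
            scores = rng.permutation(np.arange(n1 + n2, dtype=float))  # tie-free
            y = np.array([1] * n1 + [0] * n2)
            auc = roc_curve(scores, y).auc
            u = stats.mannwhitneyu(scores[:n1], scores[n1:],
                                   alternative="two-sided").statistic
            assert auc == pytest.approx(u / (n1 * n2), abs=1e-12)

    def test_ties_count_half(self):
        roc = roc_curve([0.5, 0.5], [1, 0])
        assert roc.auc == pytest.approx(0.5)

    def test_constant_scores_degenerate(self):
        roc = roc_curve([0.3] * 6, [1, 1, 1, 0, 0, 0])
        assert roc.degenerate and roc.auc == pytest.approx(0.5)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        assert roc_curve(s, y).auc == pytest.approx(roc_curve(np.exp(s), y).auc)

    def test_sensitivity_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=25)
        y = rng.integers(0, 2, 25)
        y[:2] = [0, 1]
        roc = roc_curve(s, y)
        assert np.all(np.diff(roc.sensitivity) >= 0)  # thresholds descend
        assert roc.sensitivity[0] == 0.0 and roc.sensitivity[-1] == 1.0

    def test_youden_tie_prefers_higher_sensitivity(self):
        # scores where two thresholds share max J
        roc = roc_curve([0.9, 0.6, 0.4, 0.1], [1, 1, 0, 0])
        assert roc.operating_point[1] == 1.0


class TestEvaluatePanel:
    def test_single_separating_mirna(self):
        v = np.array([[1.0], [0.9], [0.8], [-0.8], [-0.9], [-1.0]])
        nrq = make_nrq(v, ["m1"])
        labels = make_labels([1, 1, 1, 0, 0, 0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = evaluate_panel(nrq, ["m1"], labels)
        assert res.auc == 1.0

    def test_three_planted_beat_best_single(self):
        rng = np.random.default_rng(6)
        n = 90
        y = np.array([1] * 44 + [0] * 46)
        v = rng.normal(size=(n, 3)) + 0.7 * y[:, None]
        nrq = make_nrq(v, ["a", "b", "c"])
        labels = make_labels(y)
        singles = [evaluate_panel(nrq, [m], labels).auc for m in "abc"]
        combo = evaluate_panel(nrq, ["a", "b", "c"], labels).auc
        assert combo > max(singles)

    def test_noise_mirna_never_hurts_in_sample(self):
        rng = np.random.default_rng(7)
        y = np.array([1] * 20 + [0] * 20)
        v = np.column_stack([rng.normal(size=40) + y, rng.normal(size=40)])
        nrq = make_nrq(v, ["sig", "noise"])
        labels = make_labels(y)
        base = evaluate_panel(nrq, ["sig"], labels).auc
        with_noise = evaluate_panel(nrq, ["sig", "noise"], labels).auc
        assert with_noise >= base - 1e-9

    def test_missing_samples_dropped(self):
        v = np.array([[0.5], [0.4], [np.nan], [-0.4], [-0.5], [-0.6]])
        nrq = pd.DataFrame(10.0 ** v, index=[f"s{i}" for i in range(6)],
                           columns=["m"])
        labels = make_labels([1, 1, 1, 0, 0, 0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = evaluate_panel(nrq, ["m"], labels)
        assert res.n_cases == 2 and res.n_controls == 3

    def test_cv_mode_null_centered_at_half(self):
        rng = np.random.default_rng(8)
        y = np.array([1] * 22 + [0] * 23)
        nrq = make_nrq(rng.normal(size=(45, 3)), ["a", "b", "c"])
        aucs = [evaluate_panel(nrq, ["a", "b", "c"],
                               make_labels(rng.permutation(y)),
                               cv_folds=5, seed=rep).auc
                for rep in range(40)]
        assert abs(np.mean(aucs) - 0.5) < 0.06


class TestSearchCombinations:
    def test_subset_counts(self):
        rng = np.random.default_rng(9)
        y = np.array([1] * 15 + [0] * 15)
        nrq = make_nrq(rng.normal(size=(30, 4)) + 0.3 * y[:, None], list("abcd"))
        labels = make_labels(y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert len(search_combinations(nrq, ["a"], labels, 1)) == 1
            assert len(search_combinations(nrq, list("abcd"), labels, 4)) == 15

    def test_redundant_member_excluded_by_tie_break(self):
        rng = np.random.default_rng(10)
        y = np.array([1] * 30 + [0] * 30)
        a = rng.normal(size=60) + 1.2 * y
        b = rng.normal(size=60) + 1.2 * y
        c = rng.normal(size=60) + 1.2 * y
        d = a.copy()  # exact duplicate: every panel with d ties its d-free twin
        nrq = make_nrq(np.column_stack([a, b, c, d]), list("abcd"))
        labels = make_labels(y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = search_combinations(nrq, list("abcd"), labels, 4)
        assert "d" not in results[0].mirna_ids

    def test_ranking_order(self):
        rng = np.random.default_rng(11)
        y = np.array([1] * 20 + [0] * 20)
        nrq = make_nrq(rng.normal(size=(40, 3)) + 0.5 * y[:, None], list("abc"))
        labels = make_labels(y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = search_combinations(nrq, list("abc"), labels, 3)
        aucs = [r.auc for r in results]
        assert aucs == sorted(aucs, reverse=True)

    def test_absent_candidate_errors(self):
        nrq = make_nrq(np.zeros((6, 1)), ["a"])
        labels = make_labels([1, 1, 1, 0, 0, 0])
        with pytest.raises(ValueError, match="absent"):
            search_combinations(nrq, ["zz"], labels, 1)


class TestPermutationNull:
    def test_fixed_score_auc_permutation_band(self):
        """Label-permutation AUC for a fixed score: centered at 0.5, 95%
        of replicates inside [0.36, 0.64] at n = 44 + 46."""
        rng = np.random.default_rng(12)
        scores = rng.normal(size=90)
        y = np.array([1] * 44 + [0] * 46)
        aucs = np.array([roc_curve(scores, rng.permutation(y)).auc
                         for _ in range(1_000)])
        assert abs(aucs.mean() - 0.5) < 0.01
        assert np.mean((aucs >= 0.36) & (aucs <= 0.64)) >= 0.95
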