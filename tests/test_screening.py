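"""LDA screener, LOO AUC, forward selection, nested CV, and metrics."""

import numpy as np
import pandas as pd
import pytest

import oracles
from oxiscreen.screening import (
    CVReport,
    auc_score,
    compute_metrics,
    forward_select,
    loo_auc,
    loo_scores,
    metrics_from_counts,
    nested_cv,
    train_lda,
)


def gaussian_1d(rng, n=60, sep=5.0, sd=1.0):
    n1 = n // 2
    x = np.concatenate([rng.normal(sep / 2, sd, n1), rng.normal(-sep / 2, sd, n - n1)])
    y = np.concatenate([np.ones(n1, int), np.zeros(n - n1, int)])
    return x[:, None], y


class TestTrainLda:
    def test_symmetric_boundary_with_equal_priors(self, rng):
        X, y = gaussian_1d(rng, n=400)
        model = train_lda(X, y, priors=(0.5, 0.5))
        # decision boundary: score(x) = 0; solve in original units
        grid = np.linspace(-3, 3, 2001)[:, None]
        scores = model.decision_scores(grid)
        boundary = grid[np.argmin(np.abs(scores)), 0]
        assert abs(boundary) < 0.2

    def test_prior_shifts_boundary_by_closed_form(self, rng):
        """With priors (0.4, 0.6) the threshold moves toward the positive
        mean by ln(0.6/0.4) * sigma^2 / delta-mu."""
        X, y = gaussian_1d(rng, n=4000, sep=5.0, sd=1.0)
        model = train_lda(X, y, priors=(0.4, 0.6))
        grid = np.linspace(-3, 3, 4001)[:, None]
        boundary = grid[np.argmin(np.abs(model.decision_scores(grid))), 0]
        expected = np.log(0.6 / 0.4) * 1.0 / 5.0
        assert boundary == pytest.approx(expected, abs=0.1)

    def test_agrees_with_sklearn_reference(self, rng):
        """Posterior ranking matches sklearn's LDA on the same data."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = rng.standard_normal((80, 4))
        y = (X[:, 0] + 0.5 * X[:, 2] + 0.3 * rng.standard_normal(80) > 0).astype(int)
        ours = train_lda(X, y, priors=(0.4, 0.6)).posterior(X)
        ref = LinearDiscriminantAnalysis(priors=[0.6, 0.4]).fit(X, y)
        theirs = ref.predict_proba(X)[:, 1]
        np.testing.assert_allclose(ours, theirs, atol=1e-6)

    def test_missing_feature_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 2)), columns=["a", "b"])
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        model = train_lda(X, y)
        with pytest.raises(Exception, match="missing"):
            model.posterior(X.rename(columns={"b": "c"}))

    def test_singular_covariance_ridged(self, rng):
        X = rng.standard_normal((30, 1))
        X = np.hstack([X, X])  # perfectly collinear
        y = np.r_[np.ones(15, int), np.zeros(15, int)]
        model = train_lda(X, y)
        assert model.ridged
        assert np.all(np.isfinite(model.posterior(X)))


class TestAuc:
    def test_perfectly_separable(self):
        scores = np.r_[np.ones(5), np.zeros(5)]
        y = np.r_[np.ones(5, int), np.zeros(5, int)]
        assert auc_score(scores, y) == 1.0

    def test_matches_pairwise_concordance_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(8, 40))
            scores = rng.integers(0, 5, n).astype(float)  # force ties
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            assert auc_score(scores, y) == pytest.approx(
                oracles.auc_bruteforce(scores, y), abs=1e-12
            )


class TestLooAuc:
    def test_separable_feature_reaches_auc_one(self, rng):
        X, y = gaussian_1d(rng, n=60, sep=10.0, sd=0.5)
        assert loo_auc(X, y) == 1.0

    def test_null_feature_auc_near_half(self, rng):
        aucs = []
        for _ in range(60):
            X = rng.standard_normal((146, 1))
            y = np.r_[np.ones(56, int), np.zeros(90, int)]
            aucs.append(loo_auc(X, y))
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_downdate_matches_explicit_refits(self, rng):
        """The rank-one-downdate LOO scores equal brute-force refitting."""
        X = rng.standard_normal((40, 3))
        y = rng.integers(0, 2, 40)
        y[:3], y[-3:] = 1, 0
        ours = loo_scores(X, y, priors=(0.4, 0.6))
        for i in range(40):
            keep = np.ones(40, bool)
            keep[i] = False
            model = train_lda(X[keep], y[keep], priors=(0.4, 0.6))
            # score without z-scoring: compare rank-determining linear score
            X1, X0 = X[keep][y[keep] == 1], X[keep][y[keep] == 0]
            m1, m0 = X1.mean(0), X0.mean(0)
            S = (X1 - m1).T @ (X1 - m1) + (X0 - m0).T @ (X0 - m0)
            cov = S / (len(X1) + len(X0) - 2)
            w = np.linalg.solve(cov, m1 - m0)
            ref = (X[i] - 0.5 * (m1 + m0)) @ w + np.log(0.4 / 0.6)
            assert ours[i] == pytest.approx(ref, rel=1e-6, abs=1e-8)

    def test_zero_variance_subset_skipped(self):
        X = np.ones((20, 1))
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        assert loo_auc(X, y) is None


class TestForwardSelect:
    def test_perfect_feature_selected_first(self, rng):
        n = 60
        y = np.r_[np.ones(30, int), np.zeros(30, int)]
        X = pd.DataFrame({
            "noise1": rng.standard_normal(n),
            "perfect": y + 0.01 * rng.standard_normal(n),
            "noise2": rng.standard_normal(n),
        })
        selected, path = forward_select(X, y, list(X.columns), max_features=2)
        assert selected[0] == "perfect"
        assert path[0] == 1.0

    def test_duplicate_feature_adds_nothing(self, rng):
        n = 80
        y = np.r_[np.ones(40, int), np.zeros(40, int)]
        good = y + 0.5 * rng.standard_normal(n)
        weak = y + 1.0 * rng.standard_normal(n)
        X = pd.DataFrame({"good": good, "copy": good.copy(), "weak": weak})
        selected, path = forward_select(X, y, list(X.columns), max_features=3)
        # one of the identical pair enters first (tie broken lexicographically)
        assert selected[0] in ("good", "copy")
        # the weaker-but-independent feature outranks the redundant copy
        assert selected[1] == "weak"
        assert path[1] > path[0]
        # the remaining duplicate adds exactly nothing
        assert path[2] == pytest.approx(path[1], abs=1e-12)

    def test_empty_pool_is_an_error(self, rng):
        from oxiscreen.screening import EmptyFeaturePoolError

        X = pd.DataFrame({"a": rng.standard_normal(20)})
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        with pytest.raises(EmptyFeaturePoolError):
            forward_select(X, y, [], max_features=2)


def _feature_cohort(rng, n1=56, n0=90, informative=("M_P", "S_LF", "M_LF_HF")):
    """Feature-matrix cohort: group difference injected only into
    ``informative`` columns, everything else exchangeable noise."""
    names = [f"F{i:02d}" for i in range(20)] + list(informative)
    y = np.r_[np.ones(n1, int), np.zeros(n0, int)]
    data = {}
    for name in names:
        x = rng.standard_normal(n1 + n0)
        if name in informative:
            x = x + 1.0 * y
        data[name] = x
    return pd.DataFrame(data), y


class TestNestedCV:
    def test_fold_sizes_for_146_subjects(self, rng):
        X, y = _feature_cohort(rng)
        report = nested_cv(X, y, n_folds=4, seed=0)
        sizes = sorted(len(f.test_index) for f in report.folds)
        assert sizes == [36, 36, 37, 37]
        # folds exhaust the cohort without overlap
        all_idx = np.concatenate([f.test_index for f in report.folds])
        assert sorted(all_idx) == list(range(146))

    def test_planted_features_reach_consensus(self, rng):
        X, y = _feature_cohort(rng)
        report = nested_cv(X, y, n_folds=4, seed=1)
        for name in ("M_P", "S_LF", "M_LF_HF"):
            assert report.feature_histogram.get(name, 0) >= 3
            assert name in report.consensus_set
        assert report.mean_test_auc > 80

    def test_same_seed_reproduces_report(self, rng):
        X, y = _feature_cohort(rng)
        a = nested_cv(X, y, seed=7)
        b = nested_cv(X, y, seed=7)
        assert a.consensus_set == b.consensus_set
        assert [f.selected_features for f in a.folds] == [f.selected_features for f in b.folds]
        assert a.mean_test_auc == b.mean_test_auc

    def test_no_leak_from_test_labels(self, rng):
        """Shuffling labels of held-out subjects cannot change training-fold
        feature selections."""
        X, y = _feature_cohort(rng)
        base = nested_cv(X, y, seed=3)
        fold = base.folds[0]
        y_mod = y.copy()
        rng.shuffle(y_mod[fold.test_index])
        # refit manually on the same training indices with modified test labels
        from oxiscreen.screening import forward_select, significance_pool

        train_idx = np.setdiff1d(np.arange(len(y)), fold.test_index)
        pool = significance_pool(X.iloc[train_idx], y_mod[train_idx])
        selected, _ = forward_select(X.iloc[train_idx], y_mod[train_idx], pool,
                                     max_features=15)
        assert selected == fold.selected_features

    def test_label_independent_features_score_near_half(self, rng):
        aucs = []
        for seed in range(3):
            X = pd.DataFrame(
                rng.standard_normal((146, 15)),
                columns=[f"F{i}" for i in range(15)],
            )
            y = np.r_[np.ones(56, int), np.zeros(90, int)]
            aucs.append(nested_cv(X, y, seed=seed).mean_test_auc)
        assert 40 <= np.mean(aucs) <= 60


class TestMetrics:
    def test_reported_confusion_arithmetic(self):
        """50 TP, 6 FN, 75 TN, 15 FP: NPV 92.6%, PPV 76.9%, 44% referred."""
        m = metrics_from_counts(tp=50, fn=6, tn=75, fp=15)
        assert m["npv"] == pytest.approx(92.6, abs=0.05)
        assert m["ppv"] == pytest.approx(76.9, abs=0.05)
        assert m["referred_pct"] == pytest.approx(100 * 65 / 146, abs=1e-9)
        assert m["sensitivity"] == pytest.approx(100 * 50 / 56, abs=1e-9)

    def test_degenerate_specificity_undefined(self):
        m = compute_metrics(np.ones(5), np.ones(5, int))
        assert m["sensitivity"] == 100.0
        assert np.isnan(m["specificity"])
        assert np.isnan(m["npv"])

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 60))
            scores = rng.random(n)
            y = rng.integers(0, 2, n)
            ours = compute_metrics(scores, y, 0.5)
            ref = oracles.confusion_bruteforce(scores, y, 0.5)
            for k, v in ref.items():
                if isinstance(v, float) and np.isnan(v):
                    assert np.isnan(ours[k])
                else:
                    assert ours[k] == pytest.approx(v, abs=1e-12)

    def test_auc_consistent_with_rank_statistic(self, rng):
        scores = rng.random(50)
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 1, 0
        m = compute_metrics(scores, y)
        assert m["auc"] == pytest.approx(100 * auc_score(scores, y), abs=1e-9)
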