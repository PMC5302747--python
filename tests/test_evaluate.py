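"""Panel refinement and scoring: stepwise models, ROC/AUC, PCA, reports."""

import warnings

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import silhouette_score
from sklearn.model_selection import train_test_split

from radmarkers.evaluate import (
    StepwiseLDA,
    StepwiseLogisticAIC,
    confusion_summary,
    evaluate_panel,
    pca_scores,
    roc_auc,
)


def _split_data(n_per_class=24, n_features=6, effect_cols=(), d=2.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_class, n_features))
    y = np.repeat([0, 1], n_per_class)
    for c in effect_cols:
        X[y == 1, c] += d
    return X, y


class TestRocAuc:
    def test_perfect_and_reversed_separation(self):
        r = roc_auc(np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0]))
        assert r.auc == pytest.approx(1.0)
        r2 = roc_auc(np.array([0.1, 0.2, 0.9, 0.8]), np.array([1, 1, 0, 0]))
        assert r2.auc == pytest.approx(0.0)

    def test_constant_scores_give_half(self):
        r = roc_auc(np.zeros(6), np.array([1, 1, 1, 0, 0, 0]))
        assert r.auc == pytest.approx(0.5)

    def test_three_quarters_by_pair_counting(self):
        # concordant pairs: (0.9,0.5),(0.9,0.1),(0.3,0.1); discordant: (0.3,0.5)
        r = roc_auc(np.array([0.9, 0.3, 0.5, 0.1]), np.array([1, 1, 0, 0]))
        assert r.auc == pytest.approx(0.75)

    def test_endpoints_anchor_the_curve(self):
        r = roc_auc(np.array([0.3, 0.7, 0.2, 0.9]), np.array([0, 1, 0, 1]))
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    @pytest.mark.parametrize("seed", range(20))
    def test_trapezoid_equals_pair_concordance(self, seed):
        """The trapezoidal area equals the tie-half-credited concordance
        count on random instances, including heavily tied integer scores."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        y = np.zeros(n, dtype=int)
        y[rng.choice(n, size=int(rng.integers(2, n - 1)), replace=False)] = 1
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        scores = (rng.integers(0, 5, n) if seed % 2 else rng.normal(size=n)).astype(float)
        r = roc_auc(scores, y)
        pos, neg = scores[y == 1], scores[y == 0]
        gt = (pos[:, None] > neg[None, :]).sum()
        eq = (pos[:, None] == neg[None, :]).sum()
        expected = (gt + 0.5 * eq) / (len(pos) * len(neg))
        assert r.auc == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_score_negation_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 4, 30).astype(float)
        y = rng.integers(0, 2, 30)
        if y.sum() in (0, 30):
            y[0] = 1 - y[0]
        assert roc_auc(scores, y).auc == pytest.approx(1 - roc_auc(-scores, y).auc)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(4.0), np.ones(4))


class TestConfusion:
    def test_counts_conserve_sample_size(self):
        y = np.array([0, 0, 1, 1, 1])
        pred = np.array([0, 1, 1, 1, 0])
        c = confusion_summary(y, pred, np.array([0, 1]))
        assert c.counts.sum() == 5
        assert c.accuracy == pytest.approx(3 / 5)

    def test_constant_prediction_zeroes_one_column(self):
        y = np.array([0, 1, 1])
        c = confusion_summary(y, np.zeros(3, dtype=int), np.array([0, 1]))
        assert c.counts[:, 1].sum() == 0

    def test_unseen_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_summary(np.array([0, 2]), np.array([0, 0]), np.array([0, 1]))


class TestStepwiseLDA:
    def test_perfect_candidate_selected_alone(self):
        X, y = _split_data(effect_cols=(2,), d=10.0, seed=1)
        clf = StepwiseLDA().fit(X, y)
        assert list(clf.selected_idx_) == [2]
        assert clf.cv_accuracy_ == pytest.approx(1.0)

    def test_redundant_copy_enters_once(self):
        X, y = _split_data(n_features=3, effect_cols=(0,), d=6.0, seed=2)
        X[:, 1] = X[:, 0]  # exact duplicate of the informative column
        clf = StepwiseLDA().fit(X, y)
        assert sorted(clf.selected_idx_)[:1] == [0]
        assert not {0, 1} <= set(clf.selected_idx_)

    def test_pure_noise_panel_accuracy_near_majority(self):
        """With few noise candidates the final model's held-out accuracy
        stays near the majority rate."""
        accs = []
        for seed in range(15):
            X, y = _split_data(n_per_class=20, n_features=3, seed=seed)
            Xt, Xe, yt, ye = train_test_split(X, y, train_size=0.7,
                                              stratify=y, random_state=seed)
            clf = StepwiseLDA().fit(Xt, yt)
            accs.append((clf.predict(Xe) == ye).mean())
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_one_variable_panel_equals_gaussian_threshold_rule(self):
        """LDA restricted to one variable reproduces the closed-form
        two-Gaussian equal-variance decision rule."""
        X, y = _split_data(n_per_class=25, n_features=1, effect_cols=(0,), d=1.5, seed=3)
        clf = StepwiseLDA().fit(X, y)
        assert list(clf.selected_idx_) == [0]
        x = X[:, 0]
        m0, m1 = x[y == 0].mean(), x[y == 1].mean()
        v = (x[y == 0].var(ddof=1) * (25 - 1) + x[y == 1].var(ddof=1) * (25 - 1)) / (50 - 2)
        grid = np.linspace(x.min() - 1, x.max() + 1, 101)[:, None]
        closed = ((grid[:, 0] * (m1 - m0) / v - (m1**2 - m0**2) / (2 * v)) >= 0).astype(int)
        np.testing.assert_array_equal(clf.predict(grid), closed)

    def test_train_accuracy_dominates_test_in_expectation(self):
        tr_accs, te_accs = [], []
        for seed in range(12):
            X, y = _split_data(n_per_class=20, n_features=8, effect_cols=(0,), d=1.0,
                               seed=seed)
            Xt, Xe, yt, ye = train_test_split(X, y, train_size=0.7, stratify=y,
                                              random_state=seed)
            clf = StepwiseLDA().fit(Xt, yt)
            tr_accs.append((clf.predict(Xt) == yt).mean())
            te_accs.append((clf.predict(Xe) == ye).mean())
        assert np.mean(tr_accs) >= np.mean(te_accs) - 0.02


class TestStepwiseLogisticAIC:
    def test_null_acceptance_rate_matches_chi_square_oracle(self):
        """With one pure-noise candidate, AIC admits it iff the likelihood-
        ratio statistic exceeds 2; the admission rate over seeds must match
        P(chi2_1 > 2) ~ 0.157 within binomial error."""
        admitted = 0
        n_seeds = 120
        for seed in range(n_seeds):
            X, y = _split_data(n_per_class=20, n_features=1, seed=seed)
            clf = StepwiseLogisticAIC().fit(X, y)
            admitted += clf.selected_idx_.size > 0
        expected = 1 - stats.chi2.cdf(2.0, df=1)
        se = np.sqrt(expected * (1 - expected) / n_seeds)
        assert abs(admitted / n_seeds - expected) < 3 * se + 0.01

    def test_strong_predictor_included_and_aic_improves(self):
        X, y = _split_data(n_per_class=32, n_features=4, effect_cols=(1,), d=2.0, seed=5)
        clf = StepwiseLogisticAIC().fit(X, y)
        assert 1 in clf.selected_idx_
        null_aic = StepwiseLogisticAIC().fit(X[:, 2:3] * 0 + 1e-9, y).aic_
        assert clf.aic_ < null_aic

    def test_perfect_separation_flagged_with_usable_fallback(self):
        X, y = _split_data(n_per_class=10, n_features=2, seed=6)
        X[:, 0] = np.where(y == 1, 5.0, -5.0)
        clf = StepwiseLogisticAIC().fit(X, y)
        assert "perfect_separation" in clf.flags_
        assert (clf.predict(X) == y).all()


class TestPca:
    def test_perfectly_correlated_features_collapse_to_pc1(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=40)
        X = np.column_stack([a, 3 * a + 1])
        scores, evr, _ = pca_scores(X)
        assert evr[0] == pytest.approx(1.0)

    def test_scores_are_centered(self):
        rng = np.random.default_rng(1)
        scores, _, _ = pca_scores(rng.normal(size=(30, 4)))
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-10)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 5))
        _, _, l1 = pca_scores(X)
        _, _, l2 = pca_scores(X)
        np.testing.assert_array_equal(l1, l2)
        for comp in l1:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_zero_variance_feature_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 3))
        X[:, 1] = 2.0
        with pytest.warns(UserWarning):
            scores, _, _ = pca_scores(X)
        assert scores.shape[1] == 2

    def test_planted_groups_separate_on_score_plane(self):
        X, y = _split_data(n_per_class=20, n_features=3,
                           effect_cols=(0, 1, 2), d=3.0, seed=4)
        scores, _, _ = pca_scores(X)
        assert silhouette_score(scores[:, :2], y) > 0.3


class TestEvaluatePanel:
    def test_planted_marker_panel_reaches_high_test_auc(self, planted_dige):
        m, marker_idx = planted_dige
        y = (m.meta["dose_gy"] > 0).astype(int).to_numpy()
        X = np.log(m.values)
        idx = np.arange(len(y))
        tr, te = train_test_split(idx, train_size=0.7, stratify=y, random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = evaluate_panel(X[tr], y[tr], X[te], y[te], marker_idx,
                                 method="lda", feature_ids=m.feature_ids)
        assert rep.roc["test"].auc >= 0.85
        assert rep.confusion["learning"].counts.sum() == len(tr)
        assert rep.confusion["test"].counts.sum() == len(te)
        assert set(rep.roc) >= {"resubstitution", "cv", "test"}
        assert rep.pca["variables"]
        assert sum(sum(v) for v in rep.histograms["counts"].values()) == len(y)

    def test_empty_candidates_yield_majority_baseline(self):
        X, y = _split_data(n_per_class=10, n_features=2, seed=7)
        Xt, Xe, yt, ye = train_test_split(X, y, train_size=0.7, stratify=y,
                                          random_state=2)
        rep = evaluate_panel(Xt, yt, Xe, ye, [], method="lda")
        assert rep.panel.variables == []
        assert "empty_candidates_majority_baseline" in rep.panel.flags
        assert rep.roc["test"].auc == pytest.approx(0.5)

    def test_logistic_route_produces_coefficients(self):
        X, y = _split_data(n_per_class=24, n_features=5, effect_cols=(0,), d=2.5, seed=8)
        Xt, Xe, yt, ye = train_test_split(X, y, train_size=0.7, stratify=y,
                                          random_state=1)
        rep = evaluate_panel(Xt, yt, Xe, ye, [0, 1, 2], method="logistic")
        assert rep.panel.method == "logistic"
        assert "var0" in rep.panel.coefficients.get("beta", {})
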