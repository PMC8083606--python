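"""LDA, ROC/AUC, DeLong, cross-validation and feature selection.

scikit-learn is used only as an independent reference oracle; the
implementation under test is the package's own closed-form code.
"""

import numpy as np
import pandas as pd
import pytest

from scentinel.cohort import CohortSpec, simulate_cohort
from scentinel.discriminate import (
    backward_feature_selection,
    confusion_metrics,
    cv_evaluate,
    delong_compare,
    fit_lda,
    one_hot,
    roc_auc,
    stratified_holdout_split,
)


def _gaussian_toy(rng, n=20, sep=3.0, d=3):
    X0 = rng.normal(0, 1, size=(n, d))
    X1 = rng.normal(sep, 1, size=(n, d))
    X = np.vstack([X0, X1])
    y = np.r_[np.zeros(n, int), np.ones(n, int)]
    return X, y


class TestOneHot:
    def test_columns_and_indicators(self, default_cohort):
        fm = one_hot(default_cohort, ("anosmic", "normosmic"))
        assert fm.feature_names == [
            "detection", "intensity", "id_first", "age",
            "sex_female", "sex_male", "eth_white", "eth_nonwhite",
        ]
        assert len(fm.X) == 265
        # one-hot pairs complement to 1 for two-category variables
        assert ((fm.X["sex_female"] + fm.X["sex_male"]) == 1).all()
        assert ((fm.X["eth_white"] + fm.X["eth_nonwhite"]) == 1).all()

    def test_positive_label_encoding(self, default_cohort):
        fm = one_hot(default_cohort, ("anosmic", "normosmic"))
        assert fm.y.sum() == 154  # normosmic is the positive class

    def test_subtests_only(self, default_cohort):
        fm = one_hot(default_cohort, ("anosmic", "normosmic"),
                     include_demographics=False)
        assert fm.feature_names == ["detection", "intensity", "id_first"]

    def test_unknown_group_rejected(self, default_cohort):
        with pytest.raises(ValueError, match="unknown group"):
            one_hot(default_cohort, ("anosmic", "hyperosmic"))


class TestLda:
    def test_separable_clouds_perfect_holdout_auc(self, rng):
        X, y = _gaussian_toy(rng, n=30, sep=5.0)
        order = rng.permutation(60)
        train, hold = order[:40], order[40:]
        model = fit_lda(X[train], y[train])
        curve = roc_auc(model.decision_scores(X[hold]), y[hold])
        assert curve.auc == 1.0

    def test_weights_match_reference_implementation(self, rng):
        """Decision scores equal scikit-learn's LDA decision_function on a
        40-point toy set to 6 significant figures."""
        sklearn_lda = pytest.importorskip(
            "sklearn.discriminant_analysis"
        ).LinearDiscriminantAnalysis
        X, y = _gaussian_toy(rng, n=20, sep=2.0)
        ours = fit_lda(X, y)
        ref = sklearn_lda(solver="lsqr").fit(X, y)
        np.testing.assert_allclose(
            ours.decision_scores(X), ref.decision_function(X), rtol=1e-6
        )
        np.testing.assert_allclose(ours.weights, ref.coef_.ravel(), rtol=1e-6)

    def test_permuted_labels_chance_auc(self, default_cohort):
        fm = one_hot(default_cohort, ("anosmic", "normosmic"))
        rng = np.random.default_rng(0)
        y_perm = rng.permutation(fm.y)
        model = fit_lda(fm.X.to_numpy(float), y_perm)
        auc = roc_auc(model.decision_scores(fm.X.to_numpy(float)), y_perm).auc
        assert 0.4 <= auc <= 0.6

    def test_singular_covariance_ridge_fallback(self):
        X = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]])  # collinear
        y = np.array([0, 0, 1, 1])
        model = fit_lda(X, y)
        assert model.ridge_applied
        with pytest.raises(np.linalg.LinAlgError):
            fit_lda(X, y, ridge_fallback=False)

    def test_too_few_per_class(self):
        with pytest.raises(ValueError, match=">= 2"):
            fit_lda(np.eye(3), [0, 1, 1])

    def test_affine_rescaling_preserves_roc(self, rng):
        """LDA is equivariant under affine feature rescaling: the ROC curve
        of its scores is unchanged."""
        X, y = _gaussian_toy(rng, n=25, sep=1.5)
        scale = np.array([2.0, 0.5, 10.0])
        shift = np.array([1.0, -3.0, 100.0])
        a = roc_auc(fit_lda(X, y).decision_scores(X), y)
        b = roc_auc(fit_lda(X * scale + shift, y).decision_scores(X * scale + shift), y)
        assert a.auc == pytest.approx(b.auc, abs=1e-10)
        np.testing.assert_allclose(a.tpr, b.tpr)


class TestRocAuc:
    def test_perfectly_ranked(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]).auc == 1.0

    def test_anti_ranked(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1]).auc == 0.0

    def test_ties_equal_brute_force_concordance(self, rng):
        """Trapezoid AUC equals the O(n^2) count over all positive/negative
        pairs (ties counted one half) on tied integer scores."""
        scores = rng.integers(0, 5, size=80).astype(float)
        labels = (rng.random(80) < 0.4).astype(int)
        curve = roc_auc(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = sum(
            1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
        )
        assert curve.auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_matches_sklearn_on_random_scores(self, rng):
        roc_auc_score = pytest.importorskip("sklearn.metrics").roc_auc_score
        scores = rng.normal(size=200)
        labels = (rng.random(200) < 0.5).astype(int)
        assert roc_auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_curve_monotone_from_origin_to_one(self, rng):
        scores = rng.normal(size=50)
        labels = (rng.random(50) < 0.5).astype(int)
        c = roc_auc(scores, labels)
        assert c.fpr[0] == c.tpr[0] == 0.0
        assert c.fpr[-1] == c.tpr[-1] == 1.0
        assert (np.diff(c.fpr) >= 0).all() and (np.diff(c.tpr) >= 0).all()

    def test_score_negation_complements_auc(self, rng):
        """AUC(s) + AUC(-s) = 1 on tie-free data."""
        scores = rng.normal(size=101)  # continuous => tie-free a.s.
        labels = (rng.random(101) < 0.5).astype(int)
        assert roc_auc(scores, labels).auc + roc_auc(-scores, labels).auc == (
            pytest.approx(1.0, abs=1e-12)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_binary_feature_auc_closed_form(self, rng):
        """AUC of a single binary feature equals
        (sensitivity + specificity) / 2 of that feature."""
        feature = (rng.random(300) < 0.6).astype(int)
        labels = (rng.random(300) < 0.5).astype(int)
        curve = roc_auc(feature.astype(float), labels)
        sens = feature[labels == 1].mean()
        spec = 1 - feature[labels == 0].mean()
        assert curve.auc == pytest.approx((sens + spec) / 2, abs=1e-12)


class TestDeLong:
    def test_self_comparison_is_null(self, rng):
        scores = rng.normal(size=100)
        labels = (rng.random(100) < 0.5).astype(int)
        curve = roc_auc(scores, labels)
        z, p = delong_compare(curve, curve)
        assert z == 0.0 and p == 1.0

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=120)
        labels = (rng.random(120) < 0.5).astype(int)
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(scores), labels)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        z, p = delong_compare(a, b)
        assert z == 0.0 and p == 1.0

    def test_variance_matches_bootstrap(self, rng):
        """DeLong AUC variance within 20% of a 2000-resample bootstrap on a
        200-point toy."""
        scores = np.r_[rng.normal(0, 1, 100), rng.normal(1, 1, 100)]
        labels = np.r_[np.zeros(100, int), np.ones(100, int)]
        curve = roc_auc(scores, labels)
        boot = []
        for _ in range(2000):
            idx = rng.integers(0, 200, size=200)
            if len(np.unique(labels[idx])) < 2:
                continue
            boot.append(roc_auc(scores[idx], labels[idx]).auc)
        boot_var = np.var(boot, ddof=1)
        assert curve.auc_variance == pytest.approx(boot_var, rel=0.2)

    def test_unpaired_rejected(self, rng):
        s = rng.normal(size=40)
        y1 = np.r_[np.zeros(20, int), np.ones(20, int)]
        y2 = 1 - y1
        with pytest.raises(ValueError, match="paired"):
            delong_compare(roc_auc(s, y1), roc_auc(s, y2))


class TestCvEvaluate:
    def test_simulated_contrast_high_holdout_auc(self, default_cohort):
        """Anosmic vs normosmic on the calibrated simulator discriminates
        nearly perfectly (cf. the reported AUC 0.95 scale)."""
        fm = one_hot(default_cohort, ("anosmic", "normosmic"))
        report = cv_evaluate(fm, seed=3)
        assert report.auc >= 0.90
        assert report.cv_auc_mean >= 0.90
        assert report.n_train + report.n_holdout == 265

    def test_no_signal_features_chance_auc(self, rng):
        X = pd.DataFrame(rng.normal(size=(400, 4)),
                         columns=["a", "b", "c", "d"])
        y = (rng.random(400) < 0.5).astype(int)
        from scentinel.discriminate import FeatureMatrix
        fm = FeatureMatrix(X=X, y=y, positive_label="p", negative_label="n")
        report = cv_evaluate(fm, seed=5)
        assert 0.35 <= report.auc <= 0.65

    def test_same_seed_identical_report(self, default_cohort):
        fm = one_hot(default_cohort, ("anosmic", "normosmic"))
        assert cv_evaluate(fm, seed=9) == cv_evaluate(fm, seed=9)

    def test_holdout_disjoint_from_training(self, rng):
        y = (rng.random(100) < 0.4).astype(int)
        train, hold = stratified_holdout_split(y, 0.2, rng)
        assert not np.intersect1d(train, hold).size
        assert len(train) + len(hold) == 100
        # stratification keeps class balance within one respondent
        assert abs(y[hold].mean() - y.mean()) < 0.1

    def test_metrics_in_unit_interval(self, default_cohort):
        fm = one_hot(default_cohort, ("other", "normosmic"))
        r = cv_evaluate(fm, seed=2)
        for v in (r.auc, r.sensitivity, r.specificity, r.ppv, r.npv):
            assert 0.0 <= v <= 1.0

    def test_degenerate_margin_flagged(self):
        m = confusion_metrics(np.array([1.0, 2.0]), np.array([1, 1]), 0.0)
        assert m["degenerate_margin"]


class TestBackwardSelection:
    def test_noise_feature_eliminated_first(self, rng):
        X = pd.DataFrame({
            "signal": np.r_[rng.normal(0, 1, 100), rng.normal(3, 1, 100)],
            "noise": rng.normal(size=200),
        })
        y = np.r_[np.zeros(100, int), np.ones(100, int)]
        from scentinel.discriminate import FeatureMatrix
        fm = FeatureMatrix(X=X, y=y, positive_label="p", negative_label="n")
        history = backward_feature_selection(fm, seed=1)
        assert history[0]["eliminated_next"] == "noise"
        assert history[-1]["features"] == ["signal"]

    def test_all_noise_final_auc_near_half(self, rng):
        X = pd.DataFrame(rng.normal(size=(300, 3)), columns=["a", "b", "c"])
        y = (rng.random(300) < 0.5).astype(int)
        from scentinel.discriminate import FeatureMatrix
        fm = FeatureMatrix(X=X, y=y, positive_label="p", negative_label="n")
        history = backward_feature_selection(fm, seed=2)
        assert abs(history[-1]["cv_auc"] - 0.5) < 0.12

    def test_intensity_best_single_subtest(self, default_cohort):
        """On the calibrated simulator, intensity is the best single
        discriminator of anosmic vs normosmic (cf. reported AUC 0.94)."""
        fm = one_hot(default_cohort, ("anosmic", "normosmic"),
                     include_demographics=False)
        history = backward_feature_selection(fm, seed=4)
        assert history[-1]["features"] == ["intensity"]
        assert history[-1]["cv_auc"] > 0.85
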