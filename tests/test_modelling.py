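import numpy as np
import pytest

import cardioahi as ca
from cardioahi.modelling import (enn_clean, smote_oversample,
                                 select_probability_threshold)


class TestBalancing:
    def make_imbalanced(self, seed=0, n_maj=900, n_min=100):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 1, (n_maj, 4)),
                       rng.normal(4, 1, (n_min, 4))])
        y = np.concatenate([np.zeros(n_maj, bool), np.ones(n_min, bool)])
        return X, y

    def test_smote_reaches_parity(self):
        X, y = self.make_imbalanced()
        X2, y2 = smote_oversample(X, y, k=5, seed=0)
        assert y2.sum() == (~y2).sum() == 900

    def test_smote_synthetic_points_interpolate_minority(self):
        X, y = self.make_imbalanced()
        X2, y2 = smote_oversample(X, y, k=5, seed=0)
        new = X2[len(y):]
        lo, hi = X[y].min(axis=0), X[y].max(axis=0)
        assert np.all(new >= lo - 1e-9) and np.all(new <= hi + 1e-9)

    def test_already_balanced_noop(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (100, 3))
        y = np.arange(100) < 50
        X2, y2 = smote_oversample(X, y, k=5, seed=0)
        assert X2.shape == X.shape

    def test_minority_too_small(self):
        X, y = self.make_imbalanced(n_min=4)
        with pytest.raises(ValueError, match="k"):
            smote_oversample(X, y, k=5, seed=0)

    def test_enn_keeps_separated_classes(self):
        X, y = self.make_imbalanced()  # 4 SD apart: essentially separable
        X2, y2 = enn_clean(X, y, k=3)
        assert len(y2) >= 0.99 * len(y)

    def test_enn_removes_noise(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (500, 2))
        y = rng.random(500) < 0.5  # labels independent of position
        _, y2 = enn_clean(X, y, k=3)
        assert len(y2) < len(y)

    def test_balance_deterministic(self):
        X, y = self.make_imbalanced()
        a = ca.balance_epochs(X, y, seed=3)
        b = ca.balance_epochs(X, y, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestSelectModel:
    def folds_from(self, X, y, k=3, seed=0):
        rng = np.random.default_rng(seed)
        idx = rng.permutation(len(y))
        parts = np.array_split(idx, k)
        folds = []
        for i in range(k):
            va = parts[i]
            tr = np.concatenate([parts[j] for j in range(k) if j != i])
            folds.append(((X[tr], y[tr]), (X[va], y[va])))
        return folds

    def test_linearly_separable_tie_goes_to_logistic(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-5, 0.3, (200, 2)),
                       rng.normal(5, 0.3, (200, 2))])
        y = np.arange(400) >= 200
        kind = ca.select_model(self.folds_from(X, y))
        assert kind == "logistic_elastic_net"

    def test_quadratic_boundary_prefers_qda(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 2, (2000, 2))
        y = np.sum(X ** 2, axis=1) < 2.4  # circular boundary
        kind = ca.select_model(self.folds_from(X, y))
        assert kind == "qda"

    def test_pure_noise_pr_auc_near_prevalence(self):
        from sklearn.metrics import average_precision_score
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (3000, 3))
        y = rng.random(3000) < 0.2
        folds = self.folds_from(X, y)
        (X_tr, y_tr), (X_va, y_va) = folds[0]
        model = ca.train_classifier(X_tr, y_tr, seed=0)
        auc = average_precision_score(y_va.astype(int),
                                      model.predict_proba(X_va)[:, 1])
        assert abs(auc - y.mean()) < 0.1


class TestTrainClassifier:
    def test_monotone_in_single_separating_feature(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 500)
        y = x > 0
        model = ca.train_classifier(x[:, None], y, seed=0)
        grid = np.linspace(-3, 3, 50)[:, None]
        p = model.predict_proba(grid)[:, 1]
        assert np.all(np.diff(p) >= -1e-12)

    def test_duplicated_column_stable(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (800, 3))
        y = X[:, 0] + 0.3 * rng.normal(size=800) > 0
        m1 = ca.train_classifier(X, y, seed=0, max_iter=3000, tol=1e-5)
        X2 = np.column_stack([X, X[:, 0]])
        m2 = ca.train_classifier(X2, y, seed=0, max_iter=3000, tol=1e-5)
        p1 = m1.predict_proba(X)[:, 1]
        p2 = m2.predict_proba(X2)[:, 1]
        assert np.max(np.abs(p1 - p2)) < 0.05

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (300, 4))
        y = X[:, 0] > 0
        m1 = ca.train_classifier(X, y, seed=7)
        m2 = ca.train_classifier(X, y, seed=7)
        assert np.array_equal(m1.coef_, m2.coef_)

    def test_non_finite_rejected(self):
        X = np.ones((10, 2))
        X[3, 1] = np.nan
        with pytest.raises(ValueError, match="column"):
            ca.train_classifier(X, np.arange(10) < 5, seed=0)


class TestTheilSen:
    def test_collinear(self):
        assert ca.theil_sen_slope([0.1, 0.2, 0.3], [5, 10, 15]) == \
            pytest.approx(50.0)

    def test_outlier_resistance(self):
        # adding the outlier (0.2, 100) gives pairwise slopes
        # {50, 50, 50, 950, -850} (the equal-x pair is skipped): median 50
        x = [0.1, 0.2, 0.3, 0.2]
        y = [5, 10, 15, 100]
        slopes = []
        for i in range(4):
            for j in range(i + 1, 4):
                if x[i] != x[j]:
                    slopes.append((y[j] - y[i]) / (x[j] - x[i]))
        assert len(slopes) == 5
        assert ca.theil_sen_slope(x, y) == pytest.approx(np.median(slopes))
        assert ca.theil_sen_slope(x, y) == pytest.approx(50.0)

    def test_differs_from_least_squares(self):
        # an outlier away from the x mean drags the least-squares slope but
        # not the median of pairwise slopes
        x = np.array([0.1, 0.2, 0.3, 0.3])
        y = np.array([5.0, 10.0, 15.0, 100.0])
        assert ca.theil_sen_slope(x, y) == pytest.approx(50.0)
        ls = np.polyfit(x, y, 1)[0]
        assert abs(ls - 50.0) > 10

    def test_matches_bruteforce_random(self):
        rng = np.random.default_rng(3)
        for n in (5, 20, 120):
            x = rng.normal(0, 1, n)
            y = 3 * x + rng.normal(0, 1, n)
            slopes = [(y[j] - y[i]) / (x[j] - x[i])
                      for i in range(n) for j in range(i + 1, n)
                      if x[i] != x[j]]
            assert ca.theil_sen_slope(x, y) == \
                pytest.approx(np.median(slopes), rel=1e-12)

    def test_all_equal_x_error(self):
        with pytest.raises(ValueError, match="equal"):
            ca.theil_sen_slope([1.0, 1.0, 1.0], [1, 2, 3])

    def test_estimate_beta(self):
        labels = [np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0], bool),
                  np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], bool),
                  np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0], bool)]
        masks = [np.ones(10, bool)] * 3
        beta = ca.estimate_beta([10.0, 20.0, 30.0], labels, masks)
        assert beta == pytest.approx(50.0)


class TestThresholdSelection:
    def test_perfect_probabilities_tie_at_highest(self):
        # probabilities exactly 0/1 matching truth: kappa plateau, 0.99 wins
        probs = [np.array([1.0] * 20 + [0.0] * 80),
                 np.array([1.0] * 50 + [0.0] * 50),
                 np.array([0.0] * 100)]
        beta = 60.0
        refs = [ca.severity_from_ahi(beta * 0.2),
                ca.severity_from_ahi(beta * 0.5), "normal"]
        thr = ca.select_probability_threshold(probs, refs, beta)
        assert thr == pytest.approx(0.99)

    def test_constant_probabilities_return_highest(self):
        probs = [np.full(50, 0.5), np.full(50, 0.5)]
        thr = ca.select_probability_threshold(probs, ["mild", "mild"], 50.0)
        assert thr == pytest.approx(0.99)

    def test_constructed_window_found_by_grid(self):
        # grid thresholds in {0.61..0.70} classify all three severities
        # correctly; the highest of them, 0.70, must be returned
        beta = 60.0
        probs = [np.concatenate([np.full(10, 0.705), np.full(90, 0.1)]),
                 np.concatenate([np.full(40, 0.705), np.full(60, 0.6)]),
                 np.concatenate([np.full(60, 0.705), np.full(40, 0.7)])]
        refs = ["mild", "moderate", "severe"]
        # thr <= 0.60: rec2 detects everything -> severe (wrong);
        # 0.61..0.70: fracs 0.1/0.4/1.0 -> AHI 6/24/60 = mild/mod/severe;
        # thr >= 0.71: rec1 detects nothing -> normal (wrong)
        thr = ca.select_probability_threshold(probs, refs, beta)
        assert thr == pytest.approx(0.70)
        # cross-check with an independent exhaustive grid evaluation
        from cardioahi.evaluation import cohens_kappa
        kappas = {t: cohens_kappa(refs, [ca.severity_from_ahi(
            beta * np.mean(p >= t)) for p in probs])
            for t in np.round(np.arange(0.01, 1.0, 0.01), 2)}
        best = max(kappas.values())
        assert max(t for t, v in kappas.items() if v == best) == 0.70


class TestEstimateAhi:
    def make_estimator(self, beta, thr):
        return ca.TrainedEstimator(model_kind="logistic_elastic_net",
                                   model=None, probability_threshold=thr,
                                   beta=beta, feature_names=[])

    def test_arithmetic_and_class(self):
        est = self.make_estimator(50.0, 0.5)
        probs = np.concatenate([np.full(20, 0.9), np.full(80, 0.1)])
        out = ca.estimate_ahi(probs, est, np.ones(100, bool))
        assert out.ahi_pred == pytest.approx(10.0)
        assert out.severity == "mild"

    def test_zero_detected_normal(self):
        est = self.make_estimator(50.0, 0.5)
        out = ca.estimate_ahi(np.full(100, 0.2), est, np.ones(100, bool))
        assert out.ahi_pred == 0.0 and out.severity == "normal"

    def test_severe_boundary_inclusive(self):
        est = self.make_estimator(60.0, 0.5)
        probs = np.concatenate([np.full(60, 0.9), np.full(60, 0.1)])
        out = ca.estimate_ahi(probs, est, np.ones(120, bool))
        assert out.ahi_pred == pytest.approx(30.0)
        assert out.severity == "severe"

    def test_no_analysable_error(self):
        est = self.make_estimator(50.0, 0.5)
        with pytest.raises(ValueError, match="analysable"):
            ca.estimate_ahi(np.full(10, 0.9), est, np.zeros(10, bool))

    def test_monotone_in_threshold_and_detections(self):
        rng = np.random.default_rng(0)
        probs = rng.random(200)
        mask = np.ones(200, bool)
        ahis = [ca.estimate_ahi(probs, self.make_estimator(50.0, t),
                                mask).ahi_pred
                for t in np.linspace(0.05, 0.95, 19)]
        assert np.all(np.diff(ahis) <= 1e-12)

    def test_perfect_labels_match_derived_ahi(self):
        # with perfect predictions, Eq.-style AHI from predictions equals
        # the one from true labels exactly
        truth = np.zeros(120, bool)
        truth[:30] = True
        probs = truth.astype(float)
        est = self.make_estimator(55.0, 0.5)
        pred = ca.estimate_ahi(probs, est, np.ones(120, bool)).ahi_pred
        der = 55.0 * truth.mean()
        assert pred == der

    def test_severity_thresholds(self):
        assert ca.severity_from_ahi(4.99) == "normal"
        assert ca.severity_from_ahi(5.0) == "mild"
        assert ca.severity_from_ahi(15.0) == "moderate"
        assert ca.severity_from_ahi(30.0) == "severe"
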