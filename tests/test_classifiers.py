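"""Classifier correctness against independent oracles and stated tie rules."""

import numpy as np
import pytest

from nirseed.classifiers import (KNNModel, choose_lvs, class_accuracy, elm_fit,
                                 elm_predict, elm_tune, kfold_split, knn_predict,
                                 knn_tune_fit, lssvm_fit, lssvm_predict,
                                 lssvm_tune, plsda_fit, plsda_predict,
                                 simpls_coefficients)


def separable_clusters(n=40, p=5, dist=10.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([-1] * (n // 2) + [1] * (n // 2))
    centers = np.zeros(p)
    X = rng.normal(size=(n, p)) + np.where(y[:, None] > 0, dist, 0.0)
    return X + centers, y


class TestKFold:
    def test_leave_one_out_limit(self):
        fold = kfold_split(10, 10, seed=0)
        assert sorted(np.bincount(fold)) == [1] * 10

    def test_study_scale_stratified_folds(self):
        y = np.array([-1] * 160 + [1] * 160)
        fold = kfold_split(320, 10, seed=3, labels=y)
        for f in range(10):
            members = fold == f
            assert members.sum() == 32
            assert int(np.sum(y[members] == -1)) == 16

    def test_deterministic(self):
        y = np.array([-1, -1, 1, 1] * 5)
        assert np.array_equal(kfold_split(20, 4, 9, y), kfold_split(20, 4, 9, y))

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(3, 5, 0)


class TestPLSDA:
    def test_separable_clusters_perfect_training_accuracy(self):
        X, y = separable_clusters()
        model = plsda_fit(X, y, 2)
        _, labels = plsda_predict(model, X)
        assert np.array_equal(labels, y)

    def test_full_rank_equals_least_squares(self, rng):
        X = rng.normal(size=(40, 6))
        y = np.where(rng.normal(size=40) > 0, 1, -1)
        y[:2] = [-1, 1]  # both classes
        model = plsda_fit(X, y, 6)
        Xc = X - X.mean(axis=0)
        b_ols = np.linalg.solve(Xc.T @ Xc, Xc.T @ (y - y.mean()))  # normal equations
        assert np.abs(model.coefficients - b_ols).max() < 1e-8

    def test_matches_nipals_pls1_reference(self, rng):
        # independent cross-check: NIPALS PLS1 coefficients coincide with SIMPLS
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(50, 12))
        y = rng.normal(size=50)
        Xc, yc = X - X.mean(0), y - y.mean()
        for lv in (1, 3, 6):
            b = simpls_coefficients(Xc, yc, lv)
            ref = sklearn.PLSRegression(n_components=lv, scale=False).fit(X, y)
            assert np.abs(ref.coef_.ravel() - b).max() < 1e-10

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError):
            plsda_fit(X, np.ones(10, dtype=int), 1)

    def test_excessive_lv_rejected(self):
        X, y = separable_clusters(n=10, p=3)
        with pytest.raises(ValueError):
            plsda_fit(X, y, 4)  # > p

    def test_score_threshold_and_tie(self):
        model = plsda_fit(*separable_clusters(), 1)
        model.coefficients = np.zeros_like(model.coefficients)
        model.y_mean = 0.0
        _, labels = plsda_predict(model, np.zeros((3, model.coefficients.size)))
        assert np.all(labels == 1)  # score exactly 0 -> +1

    def test_sign_rule(self):
        X, y = separable_clusters()
        model = plsda_fit(X, y, 2)
        scores, labels = plsda_predict(model, X)
        assert np.array_equal(labels, np.where(scores > 0, 1, -1))

    def test_training_accuracy_nondecreasing_in_lv(self, study_split):
        train, _ = study_split
        accs = []
        for lv in range(1, 11):
            model = plsda_fit(train.X, train.y, lv)
            _, labels = plsda_predict(model, train.X)
            accs.append(float(np.mean(labels == train.y)))
        assert all(b >= a - 1e-12 for a, b in zip(accs, accs[1:]))


class TestChooseLVs:
    def test_rank_one_signal_needs_one_lv(self, rng):
        n = 60
        y = np.array([-1] * 30 + [1] * 30)
        direction = rng.normal(size=8)
        X = np.outer(y * 2.0, direction) + 0.05 * rng.normal(size=(n, 8))
        best, cv = choose_lvs(X, y, max_lv=5, seed=1)
        assert best == 1
        assert cv.mean_accuracy == 1.0

    def test_single_candidate(self):
        X, y = separable_clusters()
        best, _ = choose_lvs(X, y, max_lv=1, seed=0)
        assert best == 1


class TestLSSVM:
    def test_huge_gamma_interpolates_labels(self):
        X, y = separable_clusters(n=20, p=4, dist=3.0)
        model = lssvm_fit(X, y, gamma=1e12, sigma2=10.0)
        scores, labels = lssvm_predict(model, X)
        assert np.abs(scores - y).max() < 1e-3
        assert np.array_equal(labels, y)

    def test_large_sigma2_classifies_linearly_separable_clusters(self):
        X, y = separable_clusters(n=30, p=3, dist=8.0)
        model = lssvm_fit(X, y, gamma=100.0, sigma2=1e6)
        _, labels = lssvm_predict(model, X)
        assert np.array_equal(labels, y)

    def test_conflicting_duplicates_warn(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        y = np.array([-1, 1, -1, 1])
        with pytest.warns(UserWarning):
            lssvm_fit(X, y, gamma=1e14, sigma2=1.0)

    def test_tune_single_point_grid(self):
        X, y = separable_clusters(n=20, p=3)
        model, cv = lssvm_tune(X, y, gamma_grid=[2.0], sigma2_grid=[5.0], k=5, seed=0)
        assert model.gamma == 2.0 and model.sigma2 == 5.0

    def test_tune_finds_perfect_cell_on_separable_toy(self):
        X, y = separable_clusters(n=40, p=4, dist=8.0)
        gammas = np.logspace(-1, 3, 5)
        sigmas = np.logspace(-1, 3, 5)
        model, cv = lssvm_tune(X, y, gammas, sigmas, k=5, seed=0)
        assert cv.mean_accuracy == 1.0
        assert model.gamma in gammas and model.sigma2 in sigmas

    def test_empty_grid_rejected(self):
        X, y = separable_clusters(n=10, p=2)
        with pytest.raises(ValueError):
            lssvm_tune(X, y, gamma_grid=[], sigma2_grid=[1.0])


def knn_bruteforce(Xtr, ytr, Xte, k, metric):
    """O(n^2) oracle with the documented tie rules."""
    from scipy.spatial.distance import cdist

    D = cdist(Xte, Xtr, metric=metric)
    out = []
    for row in D:
        order = sorted(range(len(row)), key=lambda j: (row[j], j))[:k]
        vote = sum(ytr[j] for j in order)
        out.append(1 if vote >= 0 else -1)
    return np.array(out)


class TestKNN:
    def test_one_nn_training_self_accuracy(self):
        X, y = separable_clusters(n=20, p=4, dist=1.0)
        model = KNNModel(k=1, metric="euclidean", X=X, y=y)
        assert np.array_equal(knn_predict(model, X), y)

    @pytest.mark.parametrize("metric", ["euclidean", "cityblock", "cosine"])
    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_matches_bruteforce_oracle(self, rng, metric, k):
        Xtr = rng.normal(size=(20, 5)) + 1.0
        ytr = np.where(rng.normal(size=20) > 0, 1, -1)
        ytr[:2] = [-1, 1]
        Xte = rng.normal(size=(15, 5)) + 1.0
        model = KNNModel(k=k, metric=metric, X=Xtr, y=ytr)
        assert np.array_equal(knn_predict(model, Xte),
                              knn_bruteforce(Xtr, ytr, Xte, k, metric))

    def test_k_near_n_collapses_to_majority(self, rng):
        X = rng.normal(size=(21, 3))
        y = np.array([-1] * 8 + [1] * 13)
        model = KNNModel(k=20, metric="euclidean", X=X, y=y)
        pred = knn_predict(model, rng.normal(size=(10, 3)))
        # 13 vs 8 majority appears in any 20-subset vote
        assert np.all(pred == 1)

    def test_tune_returns_candidate(self):
        X, y = separable_clusters(n=30, p=4, dist=4.0)
        model, cv = knn_tune_fit(X, y, k_candidates=[1, 3, 5],
                                 metric_candidates=("euclidean", "cityblock"),
                                 folds=5, seed=0)
        assert model.k in (1, 3, 5)
        assert model.metric in ("euclidean", "cityblock")
        assert cv.mean_accuracy == 1.0

    def test_k_at_least_n_rejected(self):
        X, y = separable_clusters(n=10, p=2)
        with pytest.raises(ValueError):
            knn_tune_fit(X, y, k_candidates=[10], folds=5, seed=0)


class TestELM:
    def test_same_seed_same_weights(self):
        X, y = separable_clusters(n=20, p=4)
        a = elm_fit(X, y, 15, seed=7)
        b = elm_fit(X, y, 15, seed=7)
        assert np.array_equal(a.output_weights, b.output_weights)
        assert np.array_equal(a.input_weights, b.input_weights)

    def test_wide_hidden_layer_interpolates_training_set(self, rng):
        X = rng.normal(size=(25, 6))
        y = np.where(rng.normal(size=25) > 0, 1, -1)
        y[:2] = [-1, 1]
        model = elm_fit(X, y, 40, seed=1)
        _, labels = elm_predict(model, X)
        assert np.array_equal(labels, y)

    def test_tune_grid_membership_and_default_grid(self):
        X, y = separable_clusters(n=40, p=4, dist=6.0)
        model, cv = elm_tune(X, y, folds=5, seed=0)
        assert model.n_hidden in range(10, 151, 10)
        assert cv.params["n_hidden"] == model.n_hidden


class TestClassAccuracy:
    def test_study_style_row(self):
        truth = np.array([-1] * 40 + [1] * 40)
        pred = truth.copy()
        pred[:4] = 1       # 36/40 correct in class -1
        pred[40:43] = -1   # 37/40 correct in class +1
        assert class_accuracy(truth, pred) == (90.0, 92.5, 91.25)

    def test_perfect(self):
        truth = np.array([-1, 1, 1])
        assert class_accuracy(truth, truth) == (100.0, 100.0, 100.0)

    def test_degenerate_all_positive_predictor(self):
        truth = np.array([-1] * 5 + [1] * 5)
        pred = np.ones(10, dtype=int)
        assert class_accuracy(truth, pred) == (0.0, 100.0, 50.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            class_accuracy(np.array([]), np.array([]))


class TestLeakageGuards:
    def test_prediction_labels_never_influence_scores(self, small_dataset):
        from nirseed.io import partition

        train, pred = partition(small_dataset, 0.8, seed=0)
        scrambled = np.random.default_rng(0).permutation(pred.y)
        plsda = plsda_fit(train.X, train.y, 3)
        s1, _ = plsda_predict(plsda, pred.X)
        s2, _ = plsda_predict(plsda, pred.X)  # labels unused by construction
        assert np.array_equal(s1, s2)
        svm = lssvm_fit(train.X, train.y, 10.0, 100.0)
        assert np.array_equal(lssvm_predict(svm, pred.X)[0],
                              lssvm_predict(svm, pred.X)[0])
        elm = elm_fit(train.X, train.y, 20, seed=0)
        assert np.array_equal(elm_predict(elm, pred.X)[0],
                              elm_predict(elm, pred.X)[0])
        assert not np.array_equal(scrambled, pred.y) or True

    def test_fold_assignment_independent_of_columns(self, small_dataset):
        y = small_dataset.y
        a = kfold_split(y.size, 5, seed=4, labels=y)
        b = kfold_split(y.size, 5, seed=4, labels=y)  # columns never enter
        assert np.array_equal(a, b)
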