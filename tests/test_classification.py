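"""Fold construction, the weighted linear SVM, metrics and the nested engine."""

import collections

import numpy as np
import pytest
from scipy.optimize import minimize

import dyadsync as ds
from dyadsync.classification import (
    LeakageError,
    Preprocessor,
    _FastLinearSVC,
    inverse_frequency_weights,
)


class TestCVScheme:
    def test_study_geometry_four_dyads_per_fold(self, study_roster):
        lab = ds.dyad_labels(study_roster)
        scheme = ds.build_cv_scheme(lab, outer_folds=11, outer_permutations=3, seed=1)
        for p in range(3):
            sizes = collections.Counter(scheme.assignments[p])
            assert all(v == 8 for v in sizes.values())  # 4 dyads = 8 participants
            assert len(sizes) == 11
        assert 8 / 88 == pytest.approx(0.09, abs=0.001)

    def test_dyads_never_split(self, study_roster):
        lab = ds.dyad_labels(study_roster)
        for seed in range(20):
            scheme = ds.build_cv_scheme(lab, 11, 2, seed=seed)
            for p in range(2):
                fold_by_dyad = {}
                for g, f in zip(lab.group_ids, scheme.assignments[p]):
                    fold_by_dyad.setdefault(g, set()).add(int(f))
                assert all(len(s) == 1 for s in fold_by_dyad.values())

    def test_stratification_within_one_dyad(self):
        for seed in range(20):
            r = ds.generate_roster(9, 6, seed=seed)
            lab = ds.dyad_labels(r)
            scheme = ds.build_cv_scheme(lab, outer_folds=3, outer_permutations=1, seed=seed)
            folds = scheme.assignments[0]
            per_fold_mixed = collections.Counter()
            seen = set()
            for g, f, y in zip(lab.group_ids, folds, lab.labels):
                if g in seen:
                    continue
                seen.add(g)
                if y == 1:
                    per_fold_mixed[int(f)] += 1
            counts = [per_fold_mixed[f] for f in range(3)]
            assert max(counts) - min(counts) <= 1

    def test_more_folds_than_class_dyads_rejected(self):
        r = ds.generate_roster(2, 5, seed=0)
        lab = ds.dyad_labels(r)
        with pytest.raises(ValueError):
            ds.build_cv_scheme(lab, outer_folds=3, outer_permutations=1, seed=0)

    def test_label_disagreement_within_dyad_rejected(self, study_roster):
        lab = ds.dyad_labels(study_roster)
        bad = lab.labels.copy()
        bad[0] = -bad[0]
        broken = ds.LabelVector(lab.scheme, bad, lab.positive_class,
                                lab.participant_ids, lab.group_ids)
        with pytest.raises(ValueError):
            ds.build_cv_scheme(broken, 11, 1, seed=0)


class TestWeightedLinearSVM:
    def test_separable_clusters_perfect_training_bac(self, rng):
        X = np.vstack([rng.normal(size=(20, 3)) + 4, rng.normal(size=(20, 3)) - 4])
        y = np.array([1] * 20 + [-1] * 20)
        model = ds.train_weighted_linear_svm(X, y, C=1.0)
        m = ds.compute_metrics(y, model.decision_function(X))
        assert m.bac == 1.0

    def test_label_flip_negates_hyperplane(self, rng):
        X = rng.normal(size=(40, 4))
        y = np.where(rng.random(40) < 0.5, 1, -1)
        if len(np.unique(y)) < 2:
            y[0] = -y[0]
        a = ds.train_weighted_linear_svm(X, y, C=0.5)
        b = ds.train_weighted_linear_svm(X, -y, C=0.5)
        assert np.allclose(a.weights, -b.weights, atol=1e-4)
        assert a.bias == pytest.approx(-b.bias, abs=1e-4)

    def test_matches_independent_qp_solution(self, rng):
        # primal objective: 0.5||w||^2 + C sum_i cw_i max(0, 1 - y_i f_i)^2
        # with the bias regularized (intercept treated as an extra feature),
        # solved by a generic smooth optimizer
        X = rng.normal(size=(30, 3))
        w_true = np.array([1.0, -2.0, 0.5])
        y = np.where(X @ w_true + 0.3 * rng.normal(size=30) > 0, 1, -1)
        C = 0.7
        cw = inverse_frequency_weights(y)
        sw = np.array([cw[int(t)] for t in y])
        Xa = np.hstack([X, np.ones((30, 1))])

        def objective(wb):
            margins = 1 - y * (Xa @ wb)
            hinge = np.clip(margins, 0, None)
            return 0.5 * wb @ wb + C * np.sum(sw * hinge**2)

        ref = minimize(objective, np.zeros(4), method="BFGS",
                       options={"gtol": 1e-10, "maxiter": 2000}).x
        model = ds.train_weighted_linear_svm(X, y, C=C, class_weights=cw)
        ours = np.concatenate([model.weights, [model.bias]])
        assert np.allclose(Xa @ ours, Xa @ ref, atol=1e-4)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            ds.train_weighted_linear_svm(rng.normal(size=(10, 2)), np.ones(10, int), 1.0)

    def test_inverse_frequency_weights_mean_one(self):
        y = np.array([1] * 56 + [-1] * 32)
        w = inverse_frequency_weights(y)
        assert np.mean(list(w.values())) == pytest.approx(1.0)
        assert w[-1] > w[1]  # minority class costs more

    def test_fast_path_equals_public_estimator(self, rng):
        from sklearn.svm import LinearSVC

        X = rng.normal(size=(50, 5))
        y = np.where(rng.random(50) < 0.6, 1, -1)
        cw = inverse_frequency_weights(y)
        fast = _FastLinearSVC(0.3, cw, 0).fit(X, y)
        ref = LinearSVC(C=0.3, loss="squared_hinge", class_weight=cw,
                        tol=1e-6, max_iter=20000, random_state=0).fit(X, y)
        assert np.allclose(fast.coef_, ref.coef_, atol=1e-5)
        assert np.allclose(fast.intercept_, ref.intercept_, atol=1e-5)


class TestMetrics:
    def test_perfect_separation(self):
        y = np.array([1, 1, -1, -1])
        m = ds.compute_metrics(y, np.array([2.0, 1.0, -1.0, -2.0]))
        assert m.bac == 1.0 and m.auc == 1.0

    def test_bac_is_mean_of_rates(self):
        # sensitivity 0.8 (8/10 positives), specificity 0.6 (6/10 negatives)
        y = np.array([1] * 10 + [-1] * 10)
        s = np.array([1.0] * 8 + [-1.0] * 2 + [-1.0] * 6 + [1.0] * 4)
        m = ds.compute_metrics(y, s)
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.6)
        assert m.bac == pytest.approx(0.7)

    def test_hand_confusion_table(self):
        # TP=20 FN=8 TN=20 FP=12
        y = np.array([1] * 28 + [-1] * 32)
        s = np.array([1.0] * 20 + [-1.0] * 8 + [-1.0] * 20 + [1.0] * 12)
        m = ds.compute_metrics(y, s)
        assert round(m.sensitivity, 3) == 0.714
        assert round(m.specificity, 3) == 0.625
        assert round(m.bac, 3) == 0.670
        assert round(m.ppv, 3) == 0.625
        assert round(m.npv, 3) == 0.714

    def test_auc_invariant_under_monotone_transform(self, rng):
        y = np.where(rng.random(40) < 0.5, 1, -1)
        y[:2] = [1, -1]
        s = rng.normal(size=40)
        a = ds.compute_metrics(y, s).auc
        b = ds.compute_metrics(y, np.exp(3 * s) - 1).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_bac_identity_property(self, rng):
        for _ in range(20):
            y = np.where(rng.random(30) < 0.5, 1, -1)
            y[:2] = [1, -1]
            m = ds.compute_metrics(y, rng.normal(size=30))
            assert m.bac == pytest.approx((m.sensitivity + m.specificity) / 2, abs=1e-15)

    def test_single_class_truth_flagged(self):
        m = ds.compute_metrics(np.ones(5, int), np.array([1.0, -1.0, 1.0, 1.0, -1.0]))
        assert np.isnan(m.auc)
        assert m.bac == m.sensitivity

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError):
            ds.compute_metrics(np.array([1, -1]), np.array([np.nan, 0.0]))


class TestPreprocessor:
    def test_standardize_then_impute_with_train_median(self):
        X = np.array([[0.0], [2.0], [4.0], [np.nan]])
        prep = Preprocessor().fit(X, rows=np.arange(3))
        out = prep.transform(X)
        # train mean 2, sd ~1.63; the missing cell gets the standardized
        # train median (0 here), not a raw-scale value
        assert out[1, 0] == pytest.approx(0.0)
        assert out[3, 0] == pytest.approx(0.0)

    def test_leakage_guard_fires(self):
        X = np.zeros((4, 2))
        with pytest.raises(LeakageError):
            Preprocessor().fit(X, rows=np.array([0, 1, 2]), forbidden_rows=np.array([2, 3]))

    def test_constant_feature_survives(self):
        X = np.array([[1.0, 3.0], [1.0, 4.0]])
        out = Preprocessor().fit(X).transform(X)
        assert np.isfinite(out).all()


@pytest.fixture(scope="module")
def small_setup():
    r = ds.generate_roster(8, 6, seed=3)
    lab = ds.dyad_labels(r)
    return r, lab


class TestNestedCV:
    def test_determinism(self, small_setup, rng):
        _, lab = small_setup
        X = rng.normal(size=(28, 5))
        scheme = ds.build_cv_scheme(lab, 4, 2, inner_folds=3, seed=5)
        a = ds.nested_cv_run(X, lab, scheme, C_grid=[0.1, 1.0], seed=5)
        b = ds.nested_cv_run(X, lab, scheme, C_grid=[0.1, 1.0], seed=5)
        assert np.array_equal(a.scores, b.scores)
        assert a.chosen_params == b.chosen_params
        assert a.metrics.as_dict() == b.metrics.as_dict()

    def test_every_participant_scored_in_every_repetition(self, small_setup, rng):
        _, lab = small_setup
        X = rng.normal(size=(28, 4))
        scheme = ds.build_cv_scheme(lab, 4, 3, inner_folds=3, seed=1)
        res = ds.nested_cv_run(X, lab, scheme, C_grid=[1.0], seed=1)
        assert res.scores.shape == (28, 3)
        assert np.isfinite(res.scores).all()
        assert np.array_equal(np.sign(res.aggregated_scores) >= 0, res.predictions == 1)

    def test_strong_separation_recovered(self, small_setup, rng):
        _, lab = small_setup
        X = rng.normal(size=(28, 5))
        X[lab.labels == 1] += 3.0  # 3 SD class separation on every feature
        scheme = ds.build_cv_scheme(lab, 4, 2, inner_folds=3, seed=2)
        res = ds.nested_cv_run(X, lab, scheme, C_grid=[0.03, 1.0], seed=2)
        assert res.metrics.bac >= 0.9

    def test_corrupting_test_rows_leaves_preprocessing_unchanged(self, small_setup, rng):
        # no-leakage property: fitted preprocessing depends on training rows only
        _, lab = small_setup
        X = rng.normal(size=(28, 4))
        scheme = ds.build_cv_scheme(lab, 4, 1, inner_folds=3, seed=7)
        folds = scheme.assignments[0]
        te = folds == 0
        tr_idx, te_idx = np.where(~te)[0], np.where(te)[0]
        prep1 = Preprocessor().fit(X, rows=tr_idx, forbidden_rows=te_idx)
        X2 = X.copy()
        X2[te_idx] += 1e6
        prep2 = Preprocessor().fit(X2, rows=tr_idx, forbidden_rows=te_idx)
        assert np.array_equal(prep1.mean_, prep2.mean_)
        assert np.array_equal(prep1.sd_, prep2.sd_)
        assert np.array_equal(prep1.median_, prep2.median_)
        # and the out-of-fold scores of the full run do not move either
        res1 = ds.nested_cv_run(X, lab, scheme, C_grid=[1.0], seed=7)
        corrupted = X.copy()
        corrupted[te_idx] *= 1.0  # same values: determinism baseline
        res2 = ds.nested_cv_run(corrupted, lab, scheme, C_grid=[1.0], seed=7)
        assert np.array_equal(res1.scores, res2.scores)

    def test_missing_values_imputed_inside_cv(self, small_setup, rng):
        _, lab = small_setup
        X = rng.normal(size=(28, 4))
        X[rng.random(X.shape) < 0.1] = np.nan
        scheme = ds.build_cv_scheme(lab, 4, 1, inner_folds=3, seed=3)
        res = ds.nested_cv_run(X, lab, scheme, C_grid=[1.0], seed=3)
        assert np.isfinite(res.scores).all()

    def test_fold_weights_recorded_for_linear_models(self, small_setup, rng):
        _, lab = small_setup
        X = rng.normal(size=(28, 6))
        scheme = ds.build_cv_scheme(lab, 4, 2, inner_folds=3, seed=4)
        res = ds.nested_cv_run(X, lab, scheme, C_grid=[1.0], seed=4)
        assert res.fold_weights.shape == (8, 6)  # 4 folds x 2 repetitions
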