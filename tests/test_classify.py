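"""Feature assembly, leak-free scaling/PCA, SVM CV and learning curves."""

import numpy as np
import pandas as pd
import pytest

from murivol.classify import (FeatureMatrix, assemble_features, cv_linear_svm,
                              learning_curve, pca_reduce, standardize)


def wide_table(rng, n=12, p=5, group_effect=0.0, prefix="s"):
    subjects = [f"{prefix}{i:02d}" for i in range(n)]
    groups = ["UT"] * (n // 2) + ["TT"] * (n - n // 2)
    data = rng.normal(size=(n, p))
    data[np.array(groups) == "TT"] += group_effect
    df = pd.DataFrame(data, index=subjects,
                      columns=[f"struct{j}" for j in range(p)])
    df["group"] = groups
    return df


class TestAssembleFeatures:
    def test_single_mode_feature_count(self, rng):
        fm = assemble_features(wide_table(rng, p=7), None, "single")
        assert fm.X.shape == (12, 7)

    def test_combined_mode_doubles_features(self, rng):
        """Final-timepoint w-scores plus change rates: 2p features."""
        w = wide_table(rng, p=7)
        r = wide_table(rng, p=7)
        fm = assemble_features(w, r, "combined")
        assert fm.X.shape == (12, 14)

    def test_missing_subject_data_listed(self, rng):
        w = wide_table(rng)
        w.iloc[2, 0] = np.nan
        with pytest.raises(ValueError, match=w.index[2]):
            assemble_features(w, None, "single")

    def test_unknown_mode(self, rng):
        with pytest.raises(ValueError):
            assemble_features(wide_table(rng), None, "quadratic")


class TestStandardize:
    def test_self_standardization(self, rng):
        X = rng.normal(2.0, 3.0, size=(20, 6))
        tr, _, kept = standardize(X)
        assert np.allclose(tr.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(tr.std(axis=0, ddof=1), 1.0)
        assert kept == list(range(6))

    def test_train_statistics_applied_to_test(self, rng):
        X = rng.normal(size=(15, 4))
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        probe = (mu + 2 * sd)[None, :]
        _, scaled, _ = standardize(X, probe)
        assert np.allclose(scaled, 2.0)

    def test_constant_column_dropped_with_warning(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            tr, te, kept = standardize(X, X)
        assert kept == [0, 2]
        assert tr.shape[1] == te.shape[1] == 2


class TestPCA:
    def test_rank_one_needs_one_component(self, rng):
        u = rng.normal(size=(20, 1))
        v = rng.normal(size=(1, 8))
        tr, _, _, n_comp = pca_reduce(u @ v, variance_fraction=0.95)
        assert n_comp == 1

    def test_explained_variance_matches_eigendecomposition(self, rng):
        """PCA spectrum equals the eigenvalues of the train covariance."""
        X = rng.normal(size=(30, 5))
        _, _, model, _ = pca_reduce(X, variance_fraction=1.0)
        cov = np.cov(X.T, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(np.sort(model.explained_variance_)[::-1], eig)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            pca_reduce(np.empty((0, 0)))

    def test_invalid_fraction(self, rng):
        with pytest.raises(ValueError):
            pca_reduce(rng.normal(size=(5, 3)), variance_fraction=1.5)


class TestCVLinearSVM:
    def test_wide_margin_perfect_auc(self, rng):
        fm_df = wide_table(rng, n=12, p=6, group_effect=8.0)
        fm = assemble_features(fm_df, None, "single")
        rep = cv_linear_svm(fm, k=3, seed=0)
        assert rep.mean_auc == 1.0

    def test_default_threefold(self, rng):
        fm = assemble_features(wide_table(rng, n=12, group_effect=8.0), None, "single")
        rep = cv_linear_svm(fm, seed=0)
        assert len(rep.fold_aucs) == 3

    def test_permuted_labels_chance_level(self, rng):
        fm = assemble_features(wide_table(rng, n=14, p=6, group_effect=3.0),
                               None, "single")
        aucs = []
        for rep_i in range(50):
            y = rng.permutation(fm.y)
            fmp = FeatureMatrix(fm.X, y, fm.feature_names, fm.subjects)
            aucs.append(cv_linear_svm(fmp, k=3, seed=rep_i).mean_auc)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_k_exceeding_class_size_rejected(self, rng):
        fm = assemble_features(wide_table(rng, n=6), None, "single")
        with pytest.raises(ValueError):
            cv_linear_svm(fm, k=4)

    def test_fold_assignments_deterministic_and_stratified(self, rng):
        fm = assemble_features(wide_table(rng, n=12, group_effect=2.0), None, "single")
        a = cv_linear_svm(fm, k=3, seed=5)
        b = cv_linear_svm(fm, k=3, seed=5)
        for x, y in zip(a.fold_assignments, b.fold_assignments):
            assert np.array_equal(x, y)
        for idx in a.fold_assignments:
            counts = np.bincount(fm.y[idx], minlength=2)
            assert abs(counts[0] - counts[1]) <= 1

    def test_no_leak_from_test_fold(self, rng):
        """Perturbing test-fold rows leaves every fold model unchanged."""
        from murivol.classify import _fold_fit_score
        fm = assemble_features(wide_table(rng, n=12, p=5, group_effect=2.0),
                               None, "single")
        train_idx = np.arange(8)
        test_idx = np.arange(8, 12)
        _, _, clf_a = _fold_fit_score(fm.X, fm.y, train_idx, test_idx, 0.95, 1.0)
        X2 = fm.X.copy()
        X2[test_idx] += rng.normal(0, 10, size=(4, 5))
        _, _, clf_b = _fold_fit_score(X2, fm.y, train_idx, test_idx, 0.95, 1.0)
        assert np.allclose(clf_a.coef_, clf_b.coef_)
        assert np.allclose(clf_a.intercept_, clf_b.intercept_)


class TestLearningCurve:
    def test_accuracy_grows_with_sample_size(self, rng):
        fm = assemble_features(wide_table(rng, n=18, p=6, group_effect=2.5),
                               None, "single")
        lc = learning_curve(fm, sizes=[6, 18], replicates=10, seed=1)
        assert lc.test_mean[-1] >= lc.test_mean[0]

    def test_training_accuracy_dominates_test(self, rng):
        fm = assemble_features(wide_table(rng, n=16, p=6, group_effect=1.0),
                               None, "single")
        lc = learning_curve(fm, sizes=[6, 10, 16], replicates=8, seed=2)
        assert np.all(lc.train_mean >= lc.test_mean - 1e-12)

    def test_single_full_size_column(self, rng):
        fm = assemble_features(wide_table(rng, n=12, p=5, group_effect=5.0),
                               None, "single")
        lc = learning_curve(fm, sizes=[12], replicates=5, seed=3)
        assert lc.sizes == [12]
        assert lc.test_mean.shape == (1,)

    def test_oversized_request_rejected(self, rng):
        fm = assemble_features(wide_table(rng, n=10), None, "single")
        with pytest.raises(ValueError):
            learning_curve(fm, sizes=[11], replicates=2, seed=0)
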