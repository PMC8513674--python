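"""Forest engine: mtry convention, OOB, proximity, importance schemes."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from microtnt import forest
from microtnt.forest import (
    HyperParams,
    derive_mtry,
    importance_corrected_janitza,
    importance_permutation_altmann,
    predict,
    proximity_matrix,
    select_top_features,
    shuffle_columns,
    train_forest,
    unsupervised_forest,
)
from microtnt.io_model import ValidationError

from conftest import separable_data


class TestDeriveMtry:
    @pytest.mark.parametrize(
        "p,factor,expected", [(542, 5, 115), (41, 1, 6), (9, 13, 9), (1, 1, 1)]
    )
    def test_convention(self, p, factor, expected):
        assert derive_mtry(p, factor) == expected

    @given(st.integers(1, 10_000))
    def test_factor_one_is_floor_sqrt(self, p):
        assert derive_mtry(p, 1) == math.floor(math.sqrt(p))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            derive_mtry(0, 1)


class TestTrainForest:
    def test_separable_data_low_oob_error(self):
        X, y = separable_data(seed=1)
        model = train_forest(X, y, HyperParams(100, 1, 0))
        assert model.oob_error < 0.10

    def test_shuffled_labels_give_chance_oob(self):
        rng = np.random.default_rng(3)
        X, y = separable_data(n=80, seed=3)
        y_null = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        model = train_forest(X, y_null, HyperParams(200, 1, 7))
        assert abs(model.oob_balanced_accuracy - 0.5) < 0.1

    def test_same_seed_reproducible(self):
        X, y = separable_data(seed=2)
        a = train_forest(X, y, HyperParams(60, 2, 9))
        b = train_forest(X, y, HyperParams(60, 2, 9))
        pd.testing.assert_series_equal(a.oob_pred, b.oob_pred)
        pd.testing.assert_frame_equal(a.oob_votes, b.oob_votes)

    def test_single_class_rejected(self):
        X, _ = separable_data()
        y = pd.Series("present", index=X.index)
        with pytest.raises(ValidationError, match="two classes"):
            train_forest(X, y, HyperParams(10, 1, 0))

    def test_missing_values_rejected(self):
        X, y = separable_data()
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValidationError, match="missing"):
            train_forest(X, y, HyperParams(10, 1, 0))


class TestPredict:
    def test_resubstitution_near_perfect_on_separable(self):
        X, y = separable_data(seed=4)
        model = train_forest(X, y, HyperParams(50, 1, 1))
        labels, _ = predict(model, X)
        assert (labels == y).mean() > 0.95

    def test_vote_fractions_sum_to_one(self):
        X, y = separable_data(seed=5)
        model = train_forest(X, y, HyperParams(30, 1, 2))
        _, fractions = predict(model, X)
        assert np.allclose(fractions.sum(axis=1), 1.0)

    def test_feature_mismatch_rejected(self):
        X, y = separable_data(seed=6)
        model = train_forest(X, y, HyperParams(10, 1, 0))
        with pytest.raises(ValidationError, match="feature"):
            predict(model, X[list(X.columns[::-1])])

    def test_tie_broken_by_training_prevalence_then_lexicographic(self):
        assert forest._majority(
            np.array([5, 5]), ["absent", "present"], ["present", "absent"]
        ) == "present"
        assert forest._majority(
            np.array([5, 5]), ["absent", "present"], ["absent", "present"]
        ) == "absent"


class TestProximity:
    def _brute_force(self, model, X):
        leaves = model.apply(X)
        n, n_trees = leaves.shape
        P = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                P[i, j] = sum(
                    leaves[i, t] == leaves[j, t] for t in range(n_trees)
                ) / n_trees
        return P

    def test_diagonal_is_one(self):
        X, y = separable_data(n=20, seed=7)
        model = train_forest(X, y, HyperParams(25, 1, 3))
        P = proximity_matrix(model, X)
        assert np.allclose(np.diag(P.values), 1.0)

    def test_equals_brute_force_oracle(self):
        X, y = separable_data(n=10, seed=8)
        model = train_forest(X, y, HyperParams(25, 1, 4))
        P = proximity_matrix(model, X)
        assert np.array_equal(P.values, self._brute_force(model, X))

    def test_entries_bounded_and_symmetric(self):
        X, y = separable_data(n=15, seed=9)
        model = train_forest(X, y, HyperParams(40, 2, 5))
        P = proximity_matrix(model, X).values
        assert np.allclose(P, P.T)
        assert P.min() >= 0 and P.max() <= 1


class TestUnsupervisedForest:
    def test_clusters_have_higher_within_proximity(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 0.3, (15, 6))
        b = rng.normal(4, 0.3, (15, 6))
        X = pd.DataFrame(
            np.vstack([a, b]),
            index=[f"s{i:02d}" for i in range(30)],
            columns=[f"f{j}" for j in range(6)],
        )
        _, P = unsupervised_forest(X, HyperParams(300, 1, 0))
        within = (P.values[:15, :15].mean() + P.values[15:, 15:].mean()) / 2
        between = P.values[:15, 15:].mean()
        assert within > between

    def test_iid_noise_shows_no_structure(self):
        # Without real structure the discrimination cannot beat chance, and
        # the proximity matrix must not separate arbitrary sample halves.
        # (OOB accuracy sits BELOW 0.5 here: each out-of-bag sample shares
        # its exact values only with opposite-class rows, a known artifact
        # of permutation-copy synthetic data on tie-free columns.)
        rng = np.random.default_rng(11)
        X = pd.DataFrame(
            rng.normal(size=(60, 8)),
            index=[f"s{i:02d}" for i in range(60)],
            columns=[f"f{j}" for j in range(8)],
        )
        model, P = unsupervised_forest(X, HyperParams(300, 1, 1))
        assert model.oob_balanced_accuracy < 0.6
        off_diag = ~np.eye(30, dtype=bool)
        within = (
            P.values[:30, :30][off_diag].mean() + P.values[30:, 30:][off_diag].mean()
        ) / 2
        between = P.values[:30, 30:].mean()
        assert abs(within - between) < 0.02

    def test_shuffled_copy_preserves_column_marginals(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        shuffled = shuffle_columns(X, seed=5)
        for col in X.columns:
            assert np.array_equal(
                np.sort(shuffled[col].to_numpy()), np.sort(X[col].to_numpy())
            )


class TestJanitzaImportance:
    def test_planted_feature_ranks_first_with_small_p(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(
            rng.normal(size=(100, 50)),
            index=[f"s{i}" for i in range(100)],
            columns=[f"f{j}" for j in range(50)],
        )
        y = pd.Series(
            rng.permutation(["present"] * 45 + ["absent"] * 55), index=X.index
        )
        X["f0"] = X["f0"] + 1.5 * (y == "present").astype(float)
        imp = importance_corrected_janitza(X, y, HyperParams(200, 5, 7), m_models=5)
        assert imp.importance.idxmax() == "f0"
        assert imp.p_value["f0"] == imp.p_value.min()
        assert imp.p_value["f0"] < 0.05

    def test_constant_column_scores_zero_with_large_p(self):
        X, y = separable_data(n=60, p=10, seed=13)
        X["f1"] = 1.0
        imp = importance_corrected_janitza(X, y, HyperParams(100, 1, 3), m_models=2)
        assert imp.importance["f1"] <= 0
        assert imp.p_value["f1"] >= 0.5

    def test_seed_determinism(self):
        X, y = separable_data(n=40, p=8, seed=14)
        a = importance_corrected_janitza(X, y, HyperParams(50, 1, 5), m_models=2)
        b = importance_corrected_janitza(X, y, HyperParams(50, 1, 5), m_models=2)
        pd.testing.assert_series_equal(a.importance, b.importance)
        pd.testing.assert_series_equal(a.p_value, b.p_value)

    def test_all_positive_scores_raise_null_error(self):
        imp = forest.ImportanceResult(
            pd.Series([1.0], index=["a"]), pd.Series([0.5], index=["a"]), "x"
        )
        assert imp is not None  # construction sanity; the error path below
        X, y = separable_data(n=60, p=1, seed=15)
        with pytest.raises(ValidationError, match="non-positive"):
            importance_corrected_janitza(X[["f0"]], y, HyperParams(50, 1, 1), m_models=2)


class TestAltmannImportance:
    def test_observed_above_all_permutations_gives_formula_p(self):
        X, y = separable_data(n=60, p=6, seed=16)
        imp = importance_permutation_altmann(X, y, HyperParams(50, 1, 2), n_perm=20)
        assert imp.p_value["f0"] == pytest.approx(1 / 21)

    def test_p_never_zero(self):
        X, y = separable_data(n=40, p=4, seed=17)
        imp = importance_permutation_altmann(X, y, HyperParams(30, 1, 3), n_perm=5)
        assert (imp.p_value >= 1 / 6).all()

    def test_null_labels_give_unremarkable_p(self):
        rng = np.random.default_rng(18)
        X, y = separable_data(n=60, p=6, seed=18)
        y_null = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        imp = importance_permutation_altmann(X, y_null, HyperParams(50, 1, 4), n_perm=30)
        assert imp.p_value["f0"] > 0.05


class TestSelectTop:
    def _result(self):
        importance = pd.Series({"a": 0.5, "b": 0.25, "c": 0.1, "d": -0.2})
        p = pd.Series({"a": 0.001, "b": 0.001, "c": 0.5, "d": 0.9})
        return forest.ImportanceResult(importance, p, "corrected_impurity_janitza")

    def test_strict_importance_cutoff(self):
        # b sits exactly at the cutoff and must be excluded
        assert select_top_features(self._result(), 0.25, 0.01) == ["a"]

    def test_permissive_cutoffs_keep_all(self):
        assert select_top_features(self._result(), -np.inf, 1.0) == ["a", "b", "c", "d"]

    def test_ordered_by_importance_descending(self):
        selected = select_top_features(self._result(), -1.0, 0.99)
        assert selected == ["a", "b", "c", "d"]
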