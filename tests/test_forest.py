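import numpy as np
import pytest

from aortafinder.cht import CandidateROI
from aortafinder.core import NOT_VISIBLE, CircleROI, GroundTruth, ROILabel
from aortafinder.forest import (
    bootstrap_distinct_fraction,
    gini_impurity,
    label_candidates,
    oob_error,
    permutation_importance,
    predict_posteriors,
    train_forest,
)


def _cand(centre, radius):
    return CandidateROI(circle=CircleROI(centre, radius), cht_metric=0.9)


class TestLabelCandidates:
    GT = GroundTruth(aa=CircleROI((100.0, 100.0), 16.0), pda=CircleROI((150.0, 130.0), 9.0), iq=3.0)

    def test_exact_match_labelled_aa(self):
        labels = label_candidates([_cand((100.0, 100.0), 16.0)], self.GT, (220, 220), (1.0, 1.0))
        assert labels == [ROILabel.AA]

    def test_concentric_half_radius_is_na(self):
        # concentric circles r, r/2: DSC = 2(1/4)/(1+1/4) = 0.4 < 0.75
        labels = label_candidates([_cand((100.0, 100.0), 8.0)], self.GT, (220, 220), (1.0, 1.0))
        assert labels == [ROILabel.NA]

    def test_multiple_near_identical_candidates_all_positive(self):
        cands = [
            _cand((100.0, 100.0), 16.0),
            _cand((100.5, 100.0), 16.0),
            _cand((100.0, 100.5), 15.5),
        ]
        labels = label_candidates(cands, self.GT, (220, 220), (1.0, 1.0))
        assert labels == [ROILabel.AA] * 3

    def test_not_visible_truth_yields_no_positives(self):
        gt = GroundTruth(aa=NOT_VISIBLE, pda=NOT_VISIBLE, iq=0.0)
        labels = label_candidates([_cand((100.0, 100.0), 16.0)], gt, (220, 220), (1.0, 1.0))
        assert labels == [ROILabel.NA]

    def test_pda_labelled_independently(self):
        labels = label_candidates([_cand((150.0, 130.0), 9.0)], self.GT, (220, 220), (1.0, 1.0))
        assert labels == [ROILabel.PDA]


class TestGini:
    @pytest.mark.parametrize(
        "fractions,expected",
        [((1.0, 0.0, 0.0), 0.0), ((1 / 3, 1 / 3, 1 / 3), 2 / 3), ((0.5, 0.5, 0.0), 0.5)],
    )
    def test_known_values(self, fractions, expected):
        assert gini_impurity(fractions) == pytest.approx(expected)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity((0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            gini_impurity((-0.1, 0.6, 0.5))


class TestBootstrapBag:
    def test_distinct_fraction_near_632(self):
        frac = bootstrap_distinct_fraction(n=2000, n_replicates=200, seed=0)
        assert frac == pytest.approx(1 - (1 - 1 / 2000) ** 2000, abs=0.005)
        assert frac == pytest.approx(0.632, abs=0.01)


class TestTrainForest:
    def test_separable_classes_low_oob_error(self, separable_training_set):
        X, y = separable_training_set
        model = train_forest(X, y, n_trees=100, mtry=2, seed=0)
        assert model.oob_error_ < 0.02

    def test_pure_noise_labels_chance_oob_error(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(600, 5))
        y = rng.integers(1, 4, 600)
        model = train_forest(X, y, n_trees=200, mtry=2, seed=0)
        assert model.oob_error_ == pytest.approx(2 / 3, abs=0.05)

    def test_same_seed_reproducible(self, separable_training_set):
        X, y = separable_training_set
        m1 = train_forest(X, y, n_trees=30, mtry=2, seed=7)
        m2 = train_forest(X, y, n_trees=30, mtry=2, seed=7)
        assert m1.oob_error_ == m2.oob_error_
        assert all((a == b).all() for a, b in zip(m1.bags, m2.bags))

    def test_priors_are_empirical_frequencies(self, separable_training_set):
        X, y = separable_training_set
        model = train_forest(X, y, n_trees=30, mtry=2, seed=0)
        assert model.class_priors == pytest.approx([1 / 3, 1 / 3, 1 / 3])

    def test_missing_class_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="class"):
            train_forest(rng.normal(size=(50, 3)), np.repeat([1, 2], 25), n_trees=10)

    def test_mean_bag_distinct_fraction_near_632(self, separable_training_set):
        X, y = separable_training_set
        model = train_forest(X, y, n_trees=100, mtry=2, seed=0)
        n = X.shape[0]
        frac = np.mean([np.unique(b).size / n for b in model.bags])
        assert frac == pytest.approx(0.632, abs=0.02)


class TestPermutationImportance:
    def test_informative_feature_dominates_noise(self, separable_training_set):
        X, y = separable_training_set
        model = train_forest(X, y, n_trees=100, mtry=2, seed=0)
        imp = permutation_importance(model, X, y, seed=0)
        assert imp[0] == max(imp)
        assert np.all(np.abs(imp[1:]) < 0.01)

    def test_reproducible_with_seed(self, separable_training_set):
        X, y = separable_training_set
        model = train_forest(X, y, n_trees=50, mtry=2, seed=0)
        i1 = permutation_importance(model, X, y, seed=3)
        i2 = permutation_importance(model, X, y, seed=3)
        assert (i1 == i2).all()


class TestPosteriors:
    def test_rows_sum_to_one(self, separable_training_set):
        X, y = separable_training_set
        model = train_forest(X, y, n_trees=50, mtry=2, seed=0)
        post = predict_posteriors(model, X)
        assert post.shape == (X.shape[0], 3)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_training_rows_of_pure_forest_confident(self, separable_training_set):
        X, y = separable_training_set
        model = train_forest(X, y, n_trees=100, mtry=2, seed=0)
        post = predict_posteriors(model, X)
        pred = np.argmax(post, axis=1) + 1
        assert (pred == y).mean() > 0.99
        assert np.median(post.max(axis=1)) > 0.9

    def test_duplicate_rows_identical_posteriors(self, separable_training_set):
        X, y = separable_training_set
        model = train_forest(X, y, n_trees=30, mtry=2, seed=0)
        row = X[5]
        post = predict_posteriors(model, np.vstack([row, row]))
        assert (post[0] == post[1]).all()

    def test_feature_count_mismatch_rejected(self, separable_training_set):
        X, y = separable_training_set
        model = train_forest(X, y, n_trees=10, mtry=2, seed=0)
        with pytest.raises(ValueError):
            predict_posteriors(model, X[:, :3])


# ---------------------------------------------------------------------------
# Brute-force CART oracle: exhaustive-split Gini tree, independent of any
# library tree implementation.


def _brute_tree_predict(X, y):
    """Training-set predictions of an exhaustive-search unpruned Gini tree."""

    def gini(labels):
        _, counts = np.unique(labels, return_counts=True)
        f = counts / counts.sum()
        return float(np.sum(f * (1 - f)))

    def grow(idx):
        labels = y[idx]
        if np.unique(labels).size == 1:
            return int(labels[0])
        parent = gini(labels)
        best = None
        for j in range(X.shape[1]):
            values = np.unique(X[idx, j])
            for t in (values[:-1] + values[1:]) / 2:
                left = idx[X[idx, j] <= t]
                right = idx[X[idx, j] > t]
                gain = parent - (
                    len(left) / len(idx) * gini(y[left])
                    + len(right) / len(idx) * gini(y[right])
                )
                if best is None or gain > best[0] + 1e-12:
                    best = (gain, j, t, left, right)
        if best is None or best[0] <= 1e-12:
            vals, counts = np.unique(labels, return_counts=True)
            return int(vals[np.argmax(counts)])
        _, j, t, left, right = best
        return (j, t, grow(left), grow(right))

    tree = grow(np.arange(len(y)))

    def predict(row, node):
        if isinstance(node, int):
            return node
        j, t, l, r = node
        return predict(row, l if row[j] <= t else r)

    return np.array([predict(row, tree) for row in X])


def test_unpruned_tree_matches_brute_force_cart_oracle():
    """A fully grown Gini tree reproduces the exhaustive-split oracle on
    its own training set (distinct rows, so both reach purity)."""
    from sklearn.tree import DecisionTreeClassifier

    rng = np.random.default_rng(11)
    X = rng.normal(size=(150, 3)).round(2)
    # labels correlated with features but not separable by a single split
    y = 1 + ((X[:, 0] + 0.5 * X[:, 1] > 0).astype(int) + (X[:, 2] > 0.5).astype(int))
    oracle = _brute_tree_predict(X, y)
    tree = DecisionTreeClassifier(criterion="gini", random_state=0).fit(X, y)
    assert (tree.predict(X) == oracle).all()
    assert (oracle == y).all()  # unpruned tree is pure on distinct rows
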