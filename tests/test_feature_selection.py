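import itertools

import numpy as np
import pytest

from conftest import make_separable
from ilfs_ecg import feature_selection as fsel
from ilfs_ecg.exceptions import InvalidParameterError
from ilfs_ecg.feature_selection import criterion_J, nested_cv, sffs


def _planted_problem(n=300, informative=3, noise=5, shift=1.5, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(size=(n, informative + noise))
    X[y == 1, :informative] += shift
    return X, y


class TestCriterionJ:
    def test_perfectly_separated_feature_scores_one(self):
        X, y = make_separable(n=40, n_features=1, shift=10.0)
        assert criterion_J(X, y, [0], "nb", seed=0) == 1.0

    def test_permuted_labels_score_chance(self):
        """Null data: J stays at chance, on average over 20 permutations."""
        js = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 5))
            y = rng.permutation([0, 1] * 100)
            js.append(criterion_J(X, y, range(5), "nb", seed=seed))
        assert abs(np.mean(js) - 0.5) <= 0.1
        assert max(abs(j - 0.5) for j in js) <= 0.2

    def test_duplicate_feature_leaves_knn_criterion_unchanged(self):
        X, y = _planted_problem(n=100, seed=3)
        X_dup = np.column_stack([X, X[:, 0]])
        j_single = criterion_J(X, y, [0], "knn", seed=1)
        j_dup = criterion_J(X_dup, y, [0, X.shape[1]], "knn", seed=1)
        assert abs(j_single - j_dup) <= 0.02

    def test_empty_subset_rejected(self):
        X, y = make_separable()
        with pytest.raises(InvalidParameterError):
            criterion_J(X, y, [], "nb")


class TestSFFS:
    def test_kmax_one_is_single_feature_argmax(self):
        X, y = _planted_problem(n=80, seed=5)
        res = sffs(X, y, "nb", k_max=1, seed=2, folds=5)
        singles = [criterion_J(X, y, [f], "nb", folds=5, seed=2)
                   for f in range(X.shape[1])]
        assert res.best_subset == (int(np.argmax(singles)),)
        assert res.best_j == max(singles)

    def test_planted_informative_features_recovered(self):
        hits = 0
        for seed in range(20):
            X, y = _planted_problem(n=300, shift=1.5, seed=seed)
            res = sffs(X, y, "nb", k_max=4, seed=seed, folds=5)
            if {0, 1, 2} <= set(res.best_subset):
                hits += 1
        assert hits >= 18

    def test_each_subset_evaluated_at_most_once(self, monkeypatch):
        calls = []
        real = fsel.criterion_J

        def counting(X, y, subset, *args, **kwargs):
            calls.append(frozenset(subset))
            return real(X, y, subset, *args, **kwargs)

        monkeypatch.setattr(fsel, "criterion_J", counting)
        X, y = _planted_problem(n=80, seed=1)
        sffs(X, y, "nb", k_max=4, seed=0, folds=5)
        assert len(calls) == len(set(calls))

    def test_floating_exclusions_strictly_improve(self):
        X, y = _planted_problem(n=120, shift=0.8, seed=7)
        res = sffs(X, y, "nb", k_max=6, seed=0, folds=5)
        best_seen: dict[int, float] = {}
        cur = 0
        for move, _, j in res.state.trajectory:
            cur += 1 if move == "add" else -1
            if move == "remove":
                assert j > best_seen[cur]
            if j > best_seen.get(cur, -np.inf):
                best_seen[cur] = j
        assert res.accuracy_curve == [best_seen[k] for k in range(1, 7)]

    def test_curve_never_below_plain_sfs(self):
        for seed in range(5):
            X, y = _planted_problem(n=100, shift=0.7, seed=seed)
            flo = sffs(X, y, "nb", k_max=6, seed=1, folds=5)
            sfs = sffs(X, y, "nb", k_max=6, seed=1, folds=5, floating=False)
            assert all(a >= b for a, b in zip(flo.accuracy_curve, sfs.accuracy_curve))

    def test_kmax_out_of_range_rejected(self):
        X, y = make_separable(n_features=4)
        with pytest.raises(InvalidParameterError):
            sffs(X, y, "nb", k_max=5)

    def test_matches_exhaustive_search_on_small_problem(self):
        X, y = _planted_problem(n=60, informative=2, noise=3, shift=1.2, seed=9)
        n = X.shape[1]
        res = sffs(X, y, "nb", k_max=n, seed=4, folds=5)
        for k in (1, 2, 3):
            best = max(
                criterion_J(X, y, list(s), "nb", folds=5, seed=4)
                for s in itertools.combinations(range(n), k)
            )
            assert res.accuracy_curve[k - 1] <= best + 1e-12


class TestNestedCV:
    def test_outer_folds_partition_the_samples(self):
        X, y = _planted_problem(n=60, seed=2)
        folds = nested_cv(X, y, "nb", k_max=2, seed=0, outer_folds=5, inner_folds=3)
        idx = np.concatenate([f.test_index for f in folds])
        assert sorted(idx) == list(range(60))

    def test_selection_uses_training_data_only(self):
        """The subset reported for a fold must be reproducible from that
        fold's training data alone — outer test data cannot influence it."""
        from sklearn.model_selection import StratifiedKFold

        X, y = _planted_problem(n=60, seed=4)
        folds = nested_cv(X, y, "nb", k_max=2, seed=3, outer_folds=5, inner_folds=3)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=3)
        for fold, (train, test) in zip(folds, skf.split(X, y)):
            np.testing.assert_array_equal(fold.test_index, test)
            res = sffs(X[train], y[train], "nb", k_max=2,
                       seed=3 + fold.fold, folds=3)
            assert res.best_subset == fold.subset

    def test_strong_effect_gives_high_outer_accuracy(self):
        X, y = make_separable(n=80, n_features=5, shift=3.0, seed=6)
        rng = np.random.default_rng(0)
        X = np.column_stack([X, rng.normal(size=(80, 3))])
        folds = nested_cv(X, y, "nb", k_max=2, seed=1, outer_folds=5, inner_folds=5)
        acc = np.mean(np.concatenate([f.y_pred == f.y_true for f in folds]))
        assert acc >= 0.9

    def test_insufficient_class_counts_rejected(self):
        X = np.zeros((15, 3))
        y = np.array([0] * 8 + [1] * 7)
        with pytest.raises(InvalidParameterError, match="10"):
            nested_cv(X, y, "nb")
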