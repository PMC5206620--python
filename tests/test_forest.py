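"""Forest engine: bootstrap/OOB mechanics, split optimality, importances."""

import numpy as np
import pytest

from fibroselect import forest as rf


# ---------------------------------------------------------------------------
# independent oracle: exhaustive greedy CART for tiny instances
# ---------------------------------------------------------------------------

def _gini_score(y_left, y_right):
    s = 0.0
    for part in (y_left, y_right):
        n1 = float(np.sum(part))
        n0 = len(part) - n1
        s += (n1 * n1 + n0 * n0) / len(part)
    return s


def oracle_cart_predict(X, y, X_query):
    """Greedy CART grown by exhaustive enumeration of features/thresholds,
    with the same tie rules (lower feature, lower threshold) and midpoint
    thresholds; leaves predict the majority label (ties -> 0)."""

    def grow(idx):
        ysub = y[idx]
        if np.all(ysub == ysub[0]) or len(idx) < 2:
            n1 = np.sum(ysub)
            return ("leaf", 1.0 if n1 > len(idx) - n1 else 0.0)
        m = len(idx)
        n1 = float(np.sum(ysub))
        parent = (n1 * n1 + (m - n1) * (m - n1)) / m
        best, best_score = None, parent + 1e-12
        for j in range(X.shape[1]):
            vals = np.unique(X[idx, j])
            for a, b in zip(vals[:-1], vals[1:]):
                thr = (a + b) / 2.0
                left = idx[X[idx, j] <= thr]
                right = idx[X[idx, j] > thr]
                score = _gini_score(y[left], y[right])
                if score > best_score:
                    best, best_score = (j, thr), score
        if best is None:
            n1 = np.sum(ysub)
            return ("leaf", 1.0 if n1 > len(idx) - n1 else 0.0)
        j, thr = best
        return (
            "node", j, thr,
            grow(idx[X[idx, j] <= thr]),
            grow(idx[X[idx, j] > thr]),
        )

    tree = grow(np.arange(len(y)))

    def descend(node, x):
        while node[0] == "node":
            _, j, thr, left, right = node
            node = left if x[j] <= thr else right
        return node[1]

    return np.array([descend(tree, x) for x in X_query])


class TestTraining:
    def test_perfectly_separable_low_oob(self):
        X = np.linspace(-1, 1, 40).reshape(-1, 1)
        y = (X[:, 0] > 0).astype(int)
        f = rf.train(X, y, rf.ForestParams(seed=1))
        assert rf.oob_report(f, X, y).oob_error <= 0.05

    def test_coin_flip_labels_chance_level(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 5))
        y = rng.integers(0, 2, 100)
        f = rf.train(X, y, rf.ForestParams(seed=2, n_trees=300))
        assert rf.oob_report(f, X, y).oob_error == pytest.approx(0.5, abs=0.1)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 4))
        y = (X[:, 0] + rng.normal(size=30) > 0).astype(int)
        f1 = rf.train(X, y, rf.ForestParams(seed=9, n_trees=50))
        f2 = rf.train(X, y, rf.ForestParams(seed=9, n_trees=50))
        assert np.array_equal(f1.inbag, f2.inbag)
        for t1, t2 in zip(f1.trees, f2.trees):
            assert np.array_equal(t1.feature, t2.feature)
            assert np.array_equal(t1.threshold, t2.threshold)
            assert np.array_equal(t1.value, t2.value)

    def test_bootstrap_draw_size_and_oob_rate(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 3))
        y = (X[:, 0] > 0).astype(int)
        f = rf.train(X, y, rf.ForestParams(seed=4, n_trees=400))
        assert f.inbag.sum(axis=1).tolist() == [60] * 400  # n draws per tree
        oob_frac = (f.inbag == 0).mean()
        assert oob_frac == pytest.approx(np.exp(-1), abs=0.02)

    @pytest.mark.parametrize(
        "X,y,err",
        [
            (np.ones((10, 1)), np.zeros(10), "constant"),
            (np.empty((10, 0)), np.arange(10) % 2, "feature"),
            (np.ones((4, 1)), np.array([0, 1, 1, 1]), "per class"),
        ],
    )
    def test_invalid_training_inputs(self, X, y, err):
        with pytest.raises(ValueError, match=err):
            rf.train(X, y, rf.ForestParams(seed=0, n_trees=5))

    def test_mtry_exceeding_p_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        y = (X[:, 0] > 0).astype(int)
        with pytest.raises(ValueError, match="mtry"):
            rf.train(X, y, rf.ForestParams(seed=0, mtry=4))


class TestOracleEquivalence:
    def test_single_tree_equals_exhaustive_cart(self):
        """A tree with mtry=p and no bootstrap is the greedy CART that
        exhaustive enumeration builds, on every tiny instance."""
        rng = np.random.default_rng(123)
        for trial in range(60):
            n = int(rng.integers(4, 9))
            p = int(rng.integers(1, 4))
            X = np.round(rng.normal(size=(n, p)), 1)
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
                continue
            f = rf.train(
                X, y, rf.ForestParams(n_trees=1, mtry=p, bootstrap=False, seed=trial)
            )
            labels, _ = rf.predict(f, X)
            expected = oracle_cart_predict(X, y.astype(float), X)
            assert np.array_equal(labels, expected.astype(int))


class TestOobReport:
    def test_separable_confusion_diagonal(self):
        X = np.linspace(-2, 2, 50).reshape(-1, 1)
        y = (X[:, 0] > 0).astype(int)
        rep = rf.oob_report(rf.train(X, y, rf.ForestParams(seed=3)), X, y)
        off_diag = rep.confusion[0, 1] + rep.confusion[1, 0]
        assert off_diag <= 2
        assert rep.confusion.sum() == rep.n_covered

    def test_error_consistent_with_confusion(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(50, 3))
        y = (X[:, 0] + rng.normal(scale=0.7, size=50) > 0).astype(int)
        rep = rf.oob_report(rf.train(X, y, rf.ForestParams(seed=5, n_trees=100)), X, y)
        miscls = rep.confusion[0, 1] + rep.confusion[1, 0]
        assert rep.oob_error == pytest.approx(miscls / rep.n_covered)

    def test_constant_regression_target_zero_mse(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 2))
        y = np.full(20, 3.5)
        f = rf.train(X, y, rf.ForestParams(seed=1, n_trees=20), task=rf.REGRESSION)
        assert rf.oob_report(f, X, y).oob_error == 0.0

    def test_single_tree_predicts_exactly_its_oob_set(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 2))
        y = (X[:, 0] > 0).astype(int)
        f = rf.train(X, y, rf.ForestParams(seed=8, n_trees=1))
        rep = rf.oob_report(f, X, y)
        oob_idx = set(np.flatnonzero(f.inbag[0] == 0).tolist())
        assert set(rep.per_sample_pred) == oob_idx
        assert rep.n_covered + rep.n_uncovered == 30


class TestImportance:
    def _signal_noise_data(self, n=80, seed=0):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.linspace(-1, 1, n), rng.normal(size=n)])
        y = (X[:, 0] > 0).astype(int)
        return X, y

    def test_unused_feature_exactly_zero(self):
        X, y = self._signal_noise_data()
        X = np.column_stack([X, np.zeros(len(X))])  # constant: never splittable
        f = rf.train(X, y, rf.ForestParams(seed=1, n_trees=100))
        imp = rf.importance_mda(f, X, y, seed=0)
        assert all(2 not in t.used_features for t in f.trees)
        assert imp.scores[2] == 0.0

    def test_noise_feature_near_zero_signal_feature_large(self):
        X, y = self._signal_noise_data()
        f = rf.train(X, y, rf.ForestParams(seed=2))
        imp = rf.importance_mda(f, X, y, seed=1)
        assert abs(imp.scores[1]) < 0.02
        # permuting the only informative column reduces OOB accuracy to chance
        oob_acc = 1.0 - rf.oob_report(f, X, y).oob_error
        assert imp.scores[0] == pytest.approx(oob_acc - 0.5, abs=0.1)

    def test_mda_deterministic_given_seed(self):
        X, y = self._signal_noise_data(seed=3)
        f = rf.train(X, y, rf.ForestParams(seed=3, n_trees=60))
        a = rf.importance_mda(f, X, y, seed=42)
        b = rf.importance_mda(f, X, y, seed=42)
        assert a.scores == b.scores

    def test_pct_inc_mse_ranks_informative_first(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 2))
        y = X[:, 0] + rng.normal(scale=0.1, size=80)
        f = rf.train(X, y, rf.ForestParams(seed=4), task=rf.REGRESSION)
        imp = rf.importance_pct_inc_mse(f, X, y, seed=0)
        assert imp.scores[0] > 10 * max(imp.scores[1], 1e-9)

    def test_perfect_fit_regression_warns_and_zeroes(self):
        X = np.arange(20, dtype=float).reshape(-1, 1)
        y = np.full(20, 2.0)
        f = rf.train(X, y, rf.ForestParams(seed=0, n_trees=10), task=rf.REGRESSION)
        with pytest.warns(UserWarning, match="perfect fit"):
            imp = rf.importance_pct_inc_mse(f, X, y, seed=0)
        assert set(imp.scores.values()) == {0.0}

    def test_task_mismatch_rejected(self):
        X, y = self._signal_noise_data()
        f = rf.train(X, y, rf.ForestParams(seed=0, n_trees=10))
        with pytest.raises(ValueError, match="regression"):
            rf.importance_pct_inc_mse(f, X, y, seed=0)


class TestPredict:
    def test_pure_forest_recalls_training_labels(self):
        X = np.linspace(-1, 1, 20).reshape(-1, 1)
        y = (X[:, 0] > 0).astype(int)
        f = rf.train(X, y, rf.ForestParams(seed=0, n_trees=50))
        labels, frac = rf.predict(f, X)
        assert np.array_equal(labels, y)
        # far from the class boundary every bootstrap tree agrees
        interior = np.abs(X[:, 0]) > 0.3
        assert np.all((frac[interior] == 0.0) | (frac[interior] == 1.0))

    def test_tie_vote_goes_to_smaller_label(self):
        # two trees voting oppositely: fraction 0.5 must yield class 0
        X = np.array([[0.0], [1.0], [0.1], [0.9]])
        y = np.array([0, 1, 0, 1])
        f = rf.train(X, y, rf.ForestParams(seed=13, n_trees=2))
        labels, frac = rf.predict(f, np.array([[0.5]]))
        if frac[0] == 0.5:
            assert labels[0] == 0
        assert labels[0] == (1 if frac[0] > 0.5 else 0)

    def test_feature_count_mismatch_rejected(self):
        X = np.linspace(-1, 1, 20).reshape(-1, 1)
        y = (X[:, 0] > 0).astype(int)
        f = rf.train(X, y, rf.ForestParams(seed=0, n_trees=5))
        with pytest.raises(ValueError, match="features"):
            rf.predict(f, np.zeros((3, 2)))


def test_jsonl_dump_round_readable(tmp_path):
    import json

    X = np.linspace(-1, 1, 20).reshape(-1, 1)
    y = (X[:, 0] > 0).astype(int)
    f = rf.train(X, y, rf.ForestParams(seed=0, n_trees=3))
    path = tmp_path / "forest.jsonl"
    rf.forest_to_jsonl(f, path)
    lines = path.read_text().splitlines()
    header = json.loads(lines[0])
    assert header["n_trees"] == 3 and len(lines) == 4
    tree = json.loads(lines[1])
    assert set(tree) == {"feature", "threshold", "left", "right", "value"}
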