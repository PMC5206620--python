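"""Random forests with out-of-bag error and permutation importance.

An ensemble of CART trees, each grown on a bootstrap draw of the training
samples with a fresh random subset of ``mtry`` candidate features at every
node (Gini impurity decrease for classification, variance reduction for
regression). Samples left out of a tree's bootstrap are that tree's
out-of-bag (OOB) set; aggregating OOB predictions yields an internal error
estimate that behaves like an independent test set of the same size.

Feature importance is measured by permutation: the drop in OOB accuracy
when a feature's values are shuffled within each tree's OOB samples (mean
decrease in accuracy, MDA), or the percent increase in OOB mean squared
error (%IncMSE) for regression. A feature used by no tree has importance
exactly zero.

Defaults mirror the canonical forest implementation: 500 trees,
mtry = floor(sqrt(p)) for classification and max(1, floor(p/3)) for
regression, terminal node sizes 1 and 5. Binary classification only.

Determinism: one master seed spawns an independent RNG stream per tree, so
results do not depend on execution order.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ForestParams",
    "Tree",
    "Forest",
    "OobReport",
    "ImportanceReport",
    "train",
    "predict",
    "oob_report",
    "importance_mda",
    "importance_pct_inc_mse",
    "forest_to_jsonl",
]

CLASSIFICATION = "classification"
REGRESSION = "regression"


@dataclass(frozen=True)
class ForestParams:
    """Forest hyperparameters.

    ``mtry`` and ``min_node_size`` of ``None`` select the task defaults
    (floor(sqrt(p)) / 1 for classification, max(1, floor(p/3)) / 5 for
    regression). ``bootstrap=False`` trains every tree on the full sample
    (used for single-tree oracle comparisons).
    """

    n_trees: int = 500
    mtry: int | None = None
    min_node_size: int | None = None
    seed: int = 0
    bootstrap: bool = True

    def resolved(self, p: int, task: str) -> tuple[int, int]:
        """Return (mtry, min_node_size) resolved for ``p`` features."""
        if self.mtry is not None:
            mtry = self.mtry
        elif task == CLASSIFICATION:
            mtry = max(1, int(math.floor(math.sqrt(p))))
        else:
            mtry = max(1, p // 3)
        if mtry > p:
            raise ValueError(f"mtry={mtry} exceeds number of features p={p}")
        node = self.min_node_size
        if node is None:
            node = 1 if task == CLASSIFICATION else 5
        return mtry, node


@dataclass
class Tree:
    """A grown CART tree in flat-array form.

    ``feature[i] == -1`` marks a leaf. Internal node ``i`` sends samples
    with ``x[feature[i]] <= threshold[i]`` to ``left[i]``, others to
    ``right[i]``. ``value`` holds the leaf payload: majority class label
    (classification; vote ties broken toward the smaller label) or mean
    response (regression).
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    used_features: frozenset[int]

    def predict(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(X.shape[0], dtype=np.int32)
        feature, threshold = self.feature, self.threshold
        left, right = self.left, self.right
        active = np.where(feature[node] >= 0)[0]
        while active.size:
            nd = node[active]
            go_left = X[active, feature[nd]] <= threshold[nd]
            node[active] = np.where(go_left, left[nd], right[nd])
            active = active[feature[node[active]] >= 0]
        return self.value[node]


@dataclass
class Forest:
    """A trained ensemble with its bootstrap bookkeeping."""

    trees: list[Tree]
    inbag: np.ndarray  # (n_trees, n_train) bootstrap multiplicities
    task: str
    params: ForestParams
    n_features: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def oob_mask(self) -> np.ndarray:
        """(n_trees, n_train) boolean: sample is out-of-bag for the tree."""
        return self.inbag == 0


@dataclass
class OobReport:
    """Out-of-bag performance summary.

    ``oob_error`` is the misclassified fraction (classification) or mean
    squared error (regression) over samples covered by at least one OOB
    tree; ``n_uncovered`` counts samples that were in-bag for every tree
    (excluded from the error).
    """

    oob_error: float
    confusion: np.ndarray | None
    per_sample_pred: dict[int, float]
    n_covered: int
    n_uncovered: int


@dataclass
class ImportanceReport:
    """Permutation importances keyed by feature index."""

    scores: dict[int, float]
    kind: str  # "mda" or "pct_inc_mse"
    scale: bool = False


def _validate_training_data(X: np.ndarray, y: np.ndarray, task: str) -> None:
    if X.ndim != 2:
        raise ValueError("X must be a 2-D samples x features matrix")
    if X.shape[1] == 0:
        raise ValueError("training requires at least one feature")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have different numbers of samples")
    if np.isnan(X).any():
        raise ValueError("X contains missing values")
    if np.isnan(y).any():
        raise ValueError("y contains missing values")
    if task == CLASSIFICATION:
        classes = np.unique(y)
        if not np.isin(classes, (0, 1)).all():
            raise ValueError("classification labels must be binary 0/1")
        if classes.size < 2:
            raise ValueError("labels are constant; nothing to classify")
        if min(int((y == 0).sum()), int((y == 1).sum())) < 2:
            raise ValueError("need at least 2 samples per class")
    elif task != REGRESSION:
        raise ValueError(f"unknown task {task!r}")


def _best_split_classification(
    X: np.ndarray, y: np.ndarray, idx: np.ndarray, feats: np.ndarray
) -> tuple[int, float] | None:
    """Best (feature, threshold) by Gini decrease, or None if no split helps.

    Maximises sum over children of (sum of squared class counts)/child size,
    which is equivalent to minimising weighted child Gini. Ties break toward
    the lower feature index then the lower threshold.
    """
    m = idx.size
    ysub = y[idx]
    n1 = ysub.sum()
    parent = (n1 * n1 + (m - n1) * (m - n1)) / m
    best_score = parent + 1e-12
    best: tuple[int, float] | None = None
    for j in feats:
        x = X[idx, j]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        cut = xs[:-1] < xs[1:]
        if not cut.any():
            continue
        c1 = np.cumsum(ysub[order])[:-1]
        nl = np.arange(1, m)
        c0 = nl - c1
        r1 = n1 - c1
        r0 = (m - nl) - r1
        score = (c1 * c1 + c0 * c0) / nl + (r1 * r1 + r0 * r0) / (m - nl)
        score = np.where(cut, score, -np.inf)
        k = int(np.argmax(score))
        if score[k] > best_score:
            best_score = score[k]
            best = (int(j), float((xs[k] + xs[k + 1]) / 2.0))
    return best


def _best_split_regression(
    X: np.ndarray, y: np.ndarray, idx: np.ndarray, feats: np.ndarray
) -> tuple[int, float] | None:
    """Best (feature, threshold) by variance reduction, same tie rules."""
    m = idx.size
    ysub = y[idx]
    total = ysub.sum()
    parent = total * total / m
    best_score = parent + 1e-12
    best: tuple[int, float] | None = None
    for j in feats:
        x = X[idx, j]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        cut = xs[:-1] < xs[1:]
        if not cut.any():
            continue
        sl = np.cumsum(ysub[order])[:-1]
        nl = np.arange(1, m)
        sr = total - sl
        score = sl * sl / nl + sr * sr / (m - nl)
        score = np.where(cut, score, -np.inf)
        k = int(np.argmax(score))
        if score[k] > best_score:
            best_score = score[k]
            best = (int(j), float((xs[k] + xs[k + 1]) / 2.0))
    return best


def _grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    sample_idx: np.ndarray,
    task: str,
    mtry: int,
    min_node_size: int,
    rng: np.random.Generator,
) -> Tree:
    p = X.shape[1]
    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    value: list[float] = []
    used: set[int] = set()
    splitter = (
        _best_split_classification if task == CLASSIFICATION else _best_split_regression
    )

    def leaf_value(idx: np.ndarray) -> float:
        ysub = y[idx]
        if task == CLASSIFICATION:
            n1 = ysub.sum()
            n0 = idx.size - n1
            return 1.0 if n1 > n0 else 0.0  # vote tie -> smaller label
        return float(ysub.mean())

    def new_node() -> int:
        feature.append(-1)
        threshold.append(0.0)
        left.append(-1)
        right.append(-1)
        value.append(0.0)
        return len(feature) - 1

    # Explicit stack keeps recursion depth unbounded by tree depth; nodes
    # are processed left-first purely for reproducibility of RNG draws.
    root = new_node()
    stack: list[tuple[int, np.ndarray]] = [(root, sample_idx)]
    while stack:
        node, idx = stack.pop()
        m = idx.size
        ysub = y[idx]
        pure = bool((ysub == ysub[0]).all())
        if m < 2 or m <= min_node_size or pure:
            value[node] = leaf_value(idx)
            continue
        feats = np.sort(rng.choice(p, size=mtry, replace=False))
        split = splitter(X, y, idx, feats)
        if split is None:
            value[node] = leaf_value(idx)
            continue
        j, thr = split
        go_left = X[idx, j] <= thr
        left_idx = idx[go_left]
        right_idx = idx[~go_left]
        feature[node] = j
        threshold[node] = thr
        used.add(j)
        lnode, rnode = new_node(), new_node()
        left[node], right[node] = lnode, rnode
        stack.append((rnode, right_idx))
        stack.append((lnode, left_idx))

    return Tree(
        feature=np.asarray(feature, dtype=np.int32),
        threshold=np.asarray(threshold, dtype=float),
        left=np.asarray(left, dtype=np.int32),
        right=np.asarray(right, dtype=np.int32),
        value=np.asarray(value, dtype=float),
        used_features=frozenset(used),
    )


def train(
    X: np.ndarray,
    y: np.ndarray,
    params: ForestParams | None = None,
    task: str = CLASSIFICATION,
) -> Forest:
    """Grow a random forest on ``(X, y)``.

    Each tree is grown on a bootstrap draw of the same size as the training
    set (with replacement), splitting until nodes are pure, fall below the
    minimum node size, or admit no impurity-reducing split. Deterministic
    given ``params.seed``.
    """
    params = params or ForestParams()
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    _validate_training_data(X, y, task)
    if task == CLASSIFICATION:
        y = y.astype(np.int64).astype(float)
    n, p = X.shape
    mtry, min_node = params.resolved(p, task)
    if params.n_trees < 1:
        raise ValueError("n_trees must be >= 1")

    streams = np.random.SeedSequence(params.seed).spawn(params.n_trees)
    trees: list[Tree] = []
    inbag = np.zeros((params.n_trees, n), dtype=np.int32)
    for t, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        if params.bootstrap:
            draw = rng.integers(0, n, size=n)
        else:
            draw = np.arange(n)
        counts = np.bincount(draw, minlength=n)
        inbag[t] = counts
        trees.append(_grow_tree(X, y, np.sort(draw), task, mtry, min_node, rng))
    return Forest(trees=trees, inbag=inbag, task=task, params=params, n_features=p)


def predict(
    forest: Forest, X_new: np.ndarray
) -> tuple[np.ndarray, np.ndarray] | np.ndarray:
    """Predict new samples.

    Classification returns ``(labels, vote_fraction)`` where the fraction of
    trees voting for class 1 serves as a continuous score (ties at exactly
    0.5 resolve to class 0, the lexicographically smaller label).
    Regression returns the mean tree response.
    """
    X_new = np.ascontiguousarray(np.asarray(X_new, dtype=float))
    if X_new.ndim != 2 or X_new.shape[1] != forest.n_features:
        raise ValueError(
            f"expected {forest.n_features} features, got "
            f"{X_new.shape[1] if X_new.ndim == 2 else 'non-matrix'}"
        )
    acc = np.zeros(X_new.shape[0])
    for tree in forest.trees:
        acc += tree.predict(X_new)
    if forest.task == CLASSIFICATION:
        frac = acc / forest.n_trees
        return (frac > 0.5).astype(int), frac
    return acc / forest.n_trees


def oob_report(forest: Forest, X: np.ndarray, y: np.ndarray) -> OobReport:
    """Out-of-bag error, confusion matrix and per-sample OOB predictions.

    ``(X, y)`` must be the forest's training data. Each sample is predicted
    by majority vote (classification) or mean (regression) over the trees
    for which it was out-of-bag; samples in-bag for every tree are excluded
    from the error and counted in ``n_uncovered``.
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if forest.inbag.shape[1] != n or X.shape[1] != forest.n_features:
        raise ValueError("X/y do not match the forest's training data shape")
    oob = forest.oob_mask()
    votes = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    for t, tree in enumerate(forest.trees):
        mask = oob[t]
        if not mask.any():
            continue
        votes[mask] += tree.predict(X[mask])
        counts[mask] += 1
    covered = counts > 0
    n_covered = int(covered.sum())
    if n_covered == 0:
        raise ValueError("no sample is out-of-bag for any tree")

    if forest.task == CLASSIFICATION:
        # majority vote; exact ties resolve to class 0
        pred = np.where(votes[covered] * 2 > counts[covered], 1, 0)
        truth = y[covered].astype(int)
        tp = int(((pred == 1) & (truth == 1)).sum())
        tn = int(((pred == 0) & (truth == 0)).sum())
        fp = int(((pred == 1) & (truth == 0)).sum())
        fn = int(((pred == 0) & (truth == 1)).sum())
        confusion = np.array([[tn, fp], [fn, tp]])
        error = (fp + fn) / n_covered
    else:
        pred = votes[covered] / counts[covered]
        confusion = None
        error = float(np.mean((pred - y[covered]) ** 2))

    per_sample = {
        int(i): float(v)
        for i, v in zip(np.flatnonzero(covered), np.asarray(pred, dtype=float))
    }
    return OobReport(
        oob_error=float(error),
        confusion=confusion,
        per_sample_pred=per_sample,
        n_covered=n_covered,
        n_uncovered=int(n - n_covered),
    )


def _per_tree_oob_stat(
    tree: Tree, X_oob: np.ndarray, y_oob: np.ndarray, task: str
) -> float:
    pred = tree.predict(X_oob)
    if task == CLASSIFICATION:
        return float(np.mean(pred == y_oob))
    return float(np.mean((pred - y_oob) ** 2))


def importance_mda(
    forest: Forest,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    scale: bool = False,
) -> ImportanceReport:
    """Permutation importance as mean decrease in OOB accuracy.

    For each tree, the accuracy on its OOB samples is compared with the
    accuracy after permuting one feature's values within those samples; the
    importance of a feature is the mean drop over all trees. Features used
    by no tree score exactly 0. With ``scale=True`` the raw mean decrease is
    divided by its standard error over trees (the reference implementation's
    scaled importance); the default reports the raw decrease, which is what
    elimination ranking consumes.
    """
    if forest.task != CLASSIFICATION:
        raise ValueError("importance_mda requires a classification forest")
    return _permutation_importance(forest, X, y, seed, scale, kind="mda")


def importance_pct_inc_mse(
    forest: Forest,
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
) -> ImportanceReport:
    """Permutation importance as percent increase in OOB MSE.

    %IncMSE_j = 100 * mean_t(MSE_t,j-permuted - MSE_t) / mean_t(MSE_t).
    A forest with zero mean OOB MSE (perfect fit) reports 0 for every
    feature, with a warning.
    """
    if forest.task != REGRESSION:
        raise ValueError("importance_pct_inc_mse requires a regression forest")
    return _permutation_importance(forest, X, y, seed, scale=False, kind="pct_inc_mse")


def _permutation_importance(
    forest: Forest,
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    scale: bool,
    kind: str,
) -> ImportanceReport:
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if forest.inbag.shape[1] != n or p != forest.n_features:
        raise ValueError("X/y do not match the forest's training data shape")
    task = forest.task
    oob = forest.oob_mask()
    streams = np.random.SeedSequence(seed).spawn(forest.n_trees)

    # diffs[j] accumulates per-tree (baseline - permuted) accuracy for MDA,
    # or (permuted - baseline) MSE for %IncMSE; unused features stay 0.
    diffs = np.zeros((forest.n_trees, p))
    base_mse = np.zeros(forest.n_trees)
    for t, tree in enumerate(forest.trees):
        mask = oob[t]
        if not mask.any():
            continue
        rng = np.random.default_rng(streams[t])
        X_oob = X[mask]
        y_oob = y[mask]
        base = _per_tree_oob_stat(tree, X_oob, y_oob, task)
        if task == REGRESSION:
            base_mse[t] = base
        m = X_oob.shape[0]
        for j in sorted(tree.used_features):
            perm = rng.permutation(m)
            X_perm = X_oob.copy()
            X_perm[:, j] = X_oob[perm, j]
            stat = _per_tree_oob_stat(tree, X_perm, y_oob, task)
            diffs[t, j] = (base - stat) if task == CLASSIFICATION else (stat - base)

    scores: dict[int, float] = {}
    if kind == "mda":
        mean = diffs.mean(axis=0)
        if scale:
            sd = diffs.std(axis=0, ddof=1)
            se = sd / math.sqrt(forest.n_trees)
            with np.errstate(invalid="ignore", divide="ignore"):
                scaled = np.where(se > 0, mean / se, mean)
            mean = scaled
        scores = {j: float(mean[j]) for j in range(p)}
    else:
        denom = float(base_mse.mean())
        if denom == 0.0:
            warnings.warn(
                "zero mean OOB MSE (perfect fit); %IncMSE reported as 0",
                stacklevel=2,
            )
            scores = {j: 0.0 for j in range(p)}
        else:
            mean = diffs.mean(axis=0)
            scores = {j: float(100.0 * mean[j] / denom) for j in range(p)}
    return ImportanceReport(scores=scores, kind=kind, scale=scale)


def forest_to_jsonl(forest: Forest, path: str | Path) -> None:
    """Dump each tree as one JSON line (feature/threshold/children/leaf)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            json.dumps(
                {
                    "task": forest.task,
                    "n_trees": forest.n_trees,
                    "n_features": forest.n_features,
                    "seed": forest.params.seed,
                }
            )
            + "\n"
        )
        for tree in forest.trees:
            fh.write(
                json.dumps(
                    {
                        "feature": tree.feature.tolist(),
                        "threshold": tree.threshold.tolist(),
                        "left": tree.left.tolist(),
                        "right": tree.right.tolist(),
                        "value": tree.value.tolist(),
                    }
                )
                + "\n"
            )
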