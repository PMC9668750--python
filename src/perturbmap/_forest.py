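"""Random-forest separability core.

A small, fused fit-and-predict random forest specialized for the tiny
(tens of observations) training sets that arise when scoring condition
separability inside balanced subsamples or spatial neighbourhoods. The
implementation is numba-compiled because prioritization runs perform
hundreds of thousands of such fits; a library forest spends more time in
per-call overhead than in tree construction at this problem size.

Trees are fully grown CART trees (Gini impurity, bootstrap resampling,
``sqrt(n_features)`` candidate features per split), and class-probability
predictions are the forest mean of leaf class frequencies — the same
estimator family as standard random-forest classifiers, which unit tests
cross-check against scikit-learn.
"""

from __future__ import annotations

import hashlib

import numpy as np
from numba import njit
from scipy.stats import rankdata

__all__ = [
    "forest_probabilities",
    "mann_whitney_auc",
    "stratified_fold_assignments",
    "rf_cv_auc",
    "stable_rng",
]


@njit(cache=True, fastmath=True)
def _forest_scores(X, y, test_X, n_trees, mtry, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    n, n_features = X.shape
    n_test = test_X.shape[0]
    out = np.zeros(n_test)
    for _tree in range(n_trees):
        idx = np.random.randint(0, n, n)  # bootstrap sample
        tidx = np.arange(n_test)
        # node stack holds (train_lo, train_hi, test_lo, test_hi) ranges
        stack = np.empty((4 * n + 8, 4), np.int64)
        top = 0
        stack[top, 0] = 0
        stack[top, 1] = n
        stack[top, 2] = 0
        stack[top, 3] = n_test
        top += 1
        while top > 0:
            top -= 1
            lo, hi = stack[top, 0], stack[top, 1]
            tlo, thi = stack[top, 2], stack[top, 3]
            m = hi - lo
            c1 = 0
            for i in range(lo, hi):
                c1 += y[idx[i]]
            if c1 == 0 or c1 == m or m < 2:
                if thi > tlo and m > 0:
                    p = c1 / m
                    for i in range(tlo, thi):
                        out[tidx[i]] += p
                continue
            parent = 1.0 - ((c1 / m) ** 2 + ((m - c1) / m) ** 2)
            best_gain = -1.0
            best_f = -1
            best_thr = 0.0
            vals = np.empty(m)
            ys = np.empty(m, np.int64)
            for _try in range(mtry):
                f = np.random.randint(0, n_features)
                for i in range(m):
                    vals[i] = X[idx[lo + i], f]
                    ys[i] = y[idx[lo + i]]
                order = np.argsort(vals)
                left1 = 0
                for r in range(m - 1):
                    o = order[r]
                    left1 += ys[o]
                    if vals[order[r + 1]] <= vals[o]:
                        continue
                    nl = r + 1
                    nr = m - nl
                    r1 = c1 - left1
                    gl = 1.0 - ((left1 / nl) ** 2 + ((nl - left1) / nl) ** 2)
                    gr = 1.0 - ((r1 / nr) ** 2 + ((nr - r1) / nr) ** 2)
                    gain = parent - (nl * gl + nr * gr) / m
                    if gain > best_gain:
                        best_gain = gain
                        best_f = f
                        best_thr = 0.5 * (vals[o] + vals[order[r + 1]])
            if best_f < 0:
                # every sampled feature constant within the node
                p = c1 / m
                for i in range(tlo, thi):
                    out[tidx[i]] += p
                continue
            pl = lo
            for i in range(lo, hi):
                if X[idx[i], best_f] <= best_thr:
                    idx[pl], idx[i] = idx[i], idx[pl]
                    pl += 1
            tl = tlo
            for i in range(tlo, thi):
                if test_X[tidx[i], best_f] <= best_thr:
                    tidx[tl], tidx[i] = tidx[i], tidx[tl]
                    tl += 1
            stack[top, 0] = lo
            stack[top, 1] = pl
            stack[top, 2] = tlo
            stack[top, 3] = tl
            top += 1
            stack[top, 0] = pl
            stack[top, 1] = hi
            stack[top, 2] = tl
            stack[top, 3] = thi
            top += 1
    return out / n_trees


def forest_probabilities(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    n_trees: int,
    seed: int,
    mtry: int | None = None,
) -> np.ndarray:
    """Train a random forest and return P(class 1) for each test row."""
    X_train = np.asfortranarray(X_train, dtype=np.float64)
    X_test = np.asfortranarray(X_test, dtype=np.float64)
    y_train = np.ascontiguousarray(y_train, dtype=np.int64)
    if X_train.ndim != 2 or X_test.ndim != 2:
        raise ValueError("feature matrices must be 2D")
    classes = np.unique(y_train)
    if not np.array_equal(classes, np.array([0, 1])):
        raise ValueError("training labels must contain both classes 0 and 1")
    if mtry is None:
        mtry = max(1, int(round(np.sqrt(X_train.shape[1]))))
    return _forest_scores(X_train, y_train, X_test, int(n_trees), int(mtry), int(seed) & 0x7FFFFFFF)


def mann_whitney_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUROC via the Mann–Whitney U statistic; tied scores credit 0.5 per pair."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes required")
    ranks = rankdata(scores)  # average ranks for ties
    rank_sum = ranks[y_true == 1].sum()
    u = rank_sum - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def stratified_fold_assignments(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Assign each observation to one of ``n_folds`` folds, stratified by class.

    Remainder observations rotate across folds between classes so the fold
    sizes are as balanced as possible overall (40 balanced labels in 3 folds
    yields sizes 14/13/13).
    """
    y = np.asarray(y)
    folds = np.empty(len(y), dtype=np.int64)
    offset = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < n_folds:
            raise ValueError(
                f"class {cls!r} has {len(idx)} observations; need >= n_folds={n_folds}"
            )
        idx = rng.permutation(idx)
        base, rem = divmod(len(idx), n_folds)
        sizes = np.full(n_folds, base, dtype=int)
        for j in range(rem):
            sizes[(offset + j) % n_folds] += 1
        offset = (offset + rem) % n_folds
        pos = 0
        for f in range(n_folds):
            folds[idx[pos : pos + sizes[f]]] = f
            pos += sizes[f]
    return folds


def rf_cv_auc(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int,
    n_trees: int,
    rng: np.random.Generator,
) -> float:
    """Mean out-of-fold AUC of a random forest over stratified k-fold CV.

    Each fold trains on the remaining folds and scores the held-out fold;
    per-fold AUCs are averaged (robust to fold-size imbalance).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("cross-validated AUC requires both condition labels")
    if len(y) < n_folds:
        raise ValueError("fewer observations than folds")
    folds = stratified_fold_assignments(y, n_folds, rng)
    aucs = np.empty(n_folds)
    for f in range(n_folds):
        test = folds == f
        train = ~test
        seed = int(rng.integers(0, 2**31 - 1))
        scores = forest_probabilities(X[train], y[train], X[test], n_trees, seed)
        aucs[f] = mann_whitney_auc(y[test], scores)
    return float(aucs.mean())


def stable_rng(seed: int, *tokens: object) -> np.random.Generator:
    """Derive an independent RNG stream from a seed and a label path.

    The stream depends only on the seed and tokens (stable hashing), so
    per-unit results are reproducible regardless of evaluation order or the
    presence of other units.
    """
    key = ":".join([str(int(seed))] + [str(t) for t in tokens]).encode()
    digest = hashlib.blake2b(key, digest_size=8).digest()
    return np.random.default_rng(int.from_bytes(digest, "little"))
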