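"""Random forest regression with prior-weighted variable sampling.

At every decision node the subset of candidate variables is drawn *without*
replacement with probabilities proportional to per-feature weights, so that
motif-supported regulators are more likely to be offered to the split
search. With uniform (or absent) weights the procedure is an ordinary
regression forest; with a zero weight a feature can never enter a tree.

Trees are standard CART regression trees, fully grown down to a minimum
leaf size, fit on bootstrap samples. Prediction error is estimated
out-of-bag, and variable importance is the out-of-bag permutation
importance ("mean decrease accuracy"): the increase in out-of-bag MSE when
one feature's values are shuffled, averaged over shuffles, negatives
clipped to zero.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["WeightedRandomForestRegressor"]


class _Tree:
    """Flat-array CART regression tree."""

    __slots__ = ("feature", "threshold", "left", "right", "value", "oob_idx")

    def __init__(self):
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.value: list[float] = []
        self.oob_idx: np.ndarray | None = None

    def _add(self, feature=-1, threshold=np.nan, value=np.nan) -> int:
        self.feature.append(feature)
        self.threshold.append(threshold)
        self.left.append(-1)
        self.right.append(-1)
        self.value.append(value)
        return len(self.feature) - 1

    def predict(self, X: np.ndarray, rows: np.ndarray) -> np.ndarray:
        out = np.empty(len(rows))
        stack = [(0, np.arange(len(rows)))]
        while stack:
            node, sub = stack.pop()
            f = self.feature[node]
            if f < 0:
                out[sub] = self.value[node]
            else:
                go_left = X[rows[sub], f] <= self.threshold[node]
                stack.append((self.left[node], sub[go_left]))
                stack.append((self.right[node], sub[~go_left]))
        return out


def _best_split(Xc: np.ndarray, y: np.ndarray, min_leaf: int):
    """Best (column, threshold) among candidate columns, by SSE reduction.

    Returns ``None`` when no split satisfies the minimum leaf size and the
    distinct-value constraint.
    """
    n = Xc.shape[0]
    order = np.argsort(Xc, axis=0, kind="stable")
    xs = np.take_along_axis(Xc, order, axis=0)
    ys = y[order]
    csum = np.cumsum(ys, axis=0)
    total = csum[-1]
    k = np.arange(1, n, dtype=float)[:, None]  # left-child sizes
    left = csum[:-1]
    # maximizing sum_child count*mean^2 == minimizing within-node SSE
    score = left**2 / k + (total - left) ** 2 / (n - k)
    valid = (k >= min_leaf) & ((n - k) >= min_leaf) & (xs[1:] > xs[:-1])
    score[~valid] = -np.inf
    flat = int(np.argmax(score))
    i, j = divmod(flat, Xc.shape[1])
    if not np.isfinite(score[i, j]):
        return None
    thr = 0.5 * (xs[i, j] + xs[i + 1, j])
    return j, float(thr)


class WeightedRandomForestRegressor(RegressorMixin, BaseEstimator):
    """Forest of CART trees with weighted candidate-variable sampling.

    Parameters
    ----------
    n_estimators : int, default 100
        Number of trees.
    feature_weights : array-like of shape (n_features,) or None
        Nonnegative sampling weights; ``None`` means uniform. A feature with
        weight 0 is never offered to a split and therefore has importance
        exactly 0.
    max_features : int or None
        Candidate variables per node (mtry). ``None`` uses ceil(p / 3),
        the regression default.
    min_samples_leaf : int, default 5
        Minimum samples per leaf; trees are otherwise fully grown.
    n_permutations : int, default 5
        Shuffles per feature for the out-of-bag permutation importance.
    random_state : int, numpy SeedSequence/Generator, or None
        Source of all randomness (bootstraps, node sampling, shuffles).

    Attributes
    ----------
    oob_prediction_ : ndarray of shape (n_samples,)
        Out-of-bag prediction (NaN for samples in every bootstrap).
    oob_mse_ : float
        Out-of-bag mean squared error.
    permutation_importances_ : ndarray of shape (n_features,)
        Out-of-bag permutation importance, clipped at 0.
    """

    def __init__(
        self,
        n_estimators: int = 100,
        feature_weights=None,
        max_features: int | None = None,
        min_samples_leaf: int = 5,
        n_permutations: int = 5,
        random_state=None,
    ):
        self.n_estimators = n_estimators
        self.feature_weights = feature_weights
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.n_permutations = n_permutations
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _grow(self, tree, X, y, idx, probs, mtry, rng):
        node = tree._add(value=float(y[idx].mean()))
        if len(idx) < 2 * self.min_samples_leaf or np.ptp(y[idx]) == 0.0:
            return node
        m = min(mtry, int(np.count_nonzero(probs)))
        cand = rng.choice(len(probs), size=m, replace=False, p=probs)
        split = _best_split(X[np.ix_(idx, cand)], y[idx], self.min_samples_leaf)
        if split is None:
            return node
        j, thr = split
        feat = int(cand[j])
        go_left = X[idx, feat] <= thr
        tree.feature[node] = feat
        tree.threshold[node] = thr
        tree.left[node] = self._grow(tree, X, y, idx[go_left], probs, mtry, rng)
        tree.right[node] = self._grow(tree, X, y, idx[~go_left], probs, mtry, rng)
        return node

    def _oob_mse(self, X, y):
        """Out-of-bag MSE of the ensemble for a (possibly perturbed) X."""
        n = len(y)
        pred_sum = np.zeros(n)
        pred_cnt = np.zeros(n)
        for tree in self.estimators_:
            oob = tree.oob_idx
            if len(oob) == 0:
                continue
            pred_sum[oob] += tree.predict(X, oob)
            pred_cnt[oob] += 1
        covered = pred_cnt > 0
        pred = np.full(n, np.nan)
        pred[covered] = pred_sum[covered] / pred_cnt[covered]
        mse = float(np.mean((y[covered] - pred[covered]) ** 2))
        return mse, pred

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        self.n_features_in_ = p
        if self.feature_weights is None:
            w = np.ones(p)
        else:
            w = np.asarray(self.feature_weights, dtype=float)
            if w.shape != (p,):
                raise ValueError("feature_weights length must match n_features")
            if (w < 0).any():
                raise ValueError("feature_weights must be nonnegative")
        if w.sum() == 0:
            raise ValueError("no admissible regulator: all feature weights are zero")
        probs = w / w.sum()
        mtry = self.max_features or int(np.ceil(p / 3))

        if isinstance(self.random_state, np.random.SeedSequence):
            ss = self.random_state
        else:
            ss = np.random.SeedSequence(self.random_state)
        rng_boot, rng_grow, rng_perm = (
            np.random.default_rng(s) for s in ss.spawn(3)
        )

        self.estimators_ = []
        for _ in range(self.n_estimators):
            boot = rng_boot.integers(0, n, n)
            oob = np.setdiff1d(np.arange(n), boot)
            tree = _Tree()
            self._grow(tree, X, y, boot, probs, mtry, rng_grow)
            tree.oob_idx = oob
            self.estimators_.append(tree)

        self.oob_mse_, self.oob_prediction_ = self._oob_mse(X, y)

        used = set()
        for tree in self.estimators_:
            used.update(f for f in tree.feature if f >= 0)
        imp = np.zeros(p)
        for j in sorted(used):
            deltas = []
            for _ in range(self.n_permutations):
                Xp = X.copy()
                Xp[:, j] = X[rng_perm.permutation(n), j]
                mse_j, _ = self._oob_mse(Xp, y)
                deltas.append(mse_j - self.oob_mse_)
            imp[j] = max(0.0, float(np.mean(deltas)))
        self.permutation_importances_ = imp
        self.used_features_ = np.array(sorted(used), dtype=int)
        return self

    def predict(self, X):
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        rows = np.arange(len(X))
        preds = np.stack([t.predict(X, rows) for t in self.estimators_])
        return preds.mean(axis=0)
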