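"""Subsampled regression random forest with out-of-bag bookkeeping.

Trees are grown on per-tree subsamples drawn *without* replacement (default
63.2% of the data, the counterpart of the expected unique fraction of a
bootstrap sample), and every tree's in-bag index set is retained so that
out-of-bag (OOB) predictions and OOB permutation importance can be computed
exactly.  The label is the continuous training label in {0, 0.5, 1}, so every
prediction is an average of leaf means and stays within [0, 1].

Importance is the classical "mean decrease in accuracy" for a regression
forest: for each tree, the increase in that tree's OOB mean squared error when
one feature's values are permuted among the OOB samples, averaged over all
trees.  Only features actually split on by a tree can change its predictions,
which keeps the computation fast.
"""

from __future__ import annotations

import numpy as np
from sklearn.tree import DecisionTreeRegressor

from ._rng import child_rng
from .errors import DegenerateInputError, ValidationError

__all__ = ["RandomForest"]


def _resolve_max_features(max_features: int | float | str, p: int) -> int:
    if isinstance(max_features, str):
        if max_features == "third":  # regression default of the classical RF
            return max(1, p // 3)
        if max_features == "sqrt":
            return max(1, int(np.sqrt(p)))
        raise ValueError(f"unknown max_features {max_features!r}")
    if isinstance(max_features, float):
        return max(1, int(max_features * p))
    return max(1, min(int(max_features), p))


class RandomForest:
    """Bagged regression trees with per-tree subsampling and OOB accounting.

    Parameters
    ----------
    n_trees
        Number of trees (default 401).
    subsample_fraction
        Fraction of samples drawn per tree.
    replace
        Draw per-tree samples with replacement (classical bootstrap) instead
        of the default without-replacement subsampling.
    max_features
        Features considered per split; ``"third"`` = floor(p/3), min 1.
    min_samples_leaf
        Minimum samples per leaf (regression default 5).
    random_state
        Seed; same seed and data give a bit-identical forest.
    """

    def __init__(
        self,
        n_trees: int = 401,
        subsample_fraction: float = 0.632,
        replace: bool = False,
        max_features: int | float | str = "third",
        min_samples_leaf: int = 5,
        random_state: int | None = 0,
    ) -> None:
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0 < subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")
        self.n_trees = int(n_trees)
        self.subsample_fraction = float(subsample_fraction)
        self.replace = bool(replace)
        self.max_features = max_features
        self.min_samples_leaf = int(min_samples_leaf)
        self.random_state = 0 if random_state is None else int(random_state)

    # -- fitting -----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "RandomForest":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 2:
            raise ValidationError("X must be 2-dimensional")
        n, p = X.shape
        if len(y) != n:
            raise ValidationError(f"feature/label length mismatch: {n} vs {len(y)}")
        if n < 2 or p < 1:
            raise DegenerateInputError("need at least 2 samples and 1 feature")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValidationError("non-finite values in X or y")
        m = max(1, int(round(self.subsample_fraction * n)))
        mf = _resolve_max_features(self.max_features, p)
        rng = child_rng(self.random_state, "forest")
        self.trees_: list[DecisionTreeRegressor] = []
        self.inbag_ = np.zeros((self.n_trees, n), dtype=bool)
        tree_seeds = rng.integers(0, 2**31 - 1, size=self.n_trees)
        for t in range(self.n_trees):
            idx = rng.choice(n, size=m, replace=self.replace)
            tree = DecisionTreeRegressor(
                max_features=mf,
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(tree_seeds[t]),
            )
            tree.fit(X[idx], y[idx])
            self.inbag_[t, idx] = True
            self.trees_.append(tree)
        self._X32 = np.ascontiguousarray(X, dtype=np.float32)
        self._y = y
        self.n_samples_ = n
        self.n_features_ = p
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "trees_"):
            raise ValidationError("forest is not fitted")

    # -- prediction --------------------------------------------------------
    def predict(self, X: np.ndarray) -> np.ndarray:
        """Mean prediction over all trees (training samples included in-bag)."""
        self._check_fitted()
        X32 = np.ascontiguousarray(np.asarray(X), dtype=np.float32)
        acc = np.zeros(len(X32))
        for tree in self.trees_:
            acc += tree.tree_.predict(X32).ravel()
        return acc / self.n_trees

    def oob_predict(self) -> tuple[np.ndarray, np.ndarray]:
        """Out-of-bag prediction and OOB tree count per training sample.

        ``r_i`` is the mean prediction of the trees whose in-bag set excludes
        sample ``i``; samples that are in-bag for every tree get NaN.
        """
        self._check_fitted()
        sums = np.zeros(self.n_samples_)
        counts = np.zeros(self.n_samples_, dtype=int)
        for t, tree in enumerate(self.trees_):
            oob = ~self.inbag_[t]
            if not oob.any():
                continue
            sums[oob] += tree.tree_.predict(np.ascontiguousarray(self._X32[oob])).ravel()
            counts[oob] += 1
        with np.errstate(invalid="ignore"):
            preds = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        return preds, counts

    # -- importance --------------------------------------------------------
    def permutation_importance(self, rng: np.random.Generator) -> np.ndarray:
        """OOB permutation importance (mean increase in OOB squared error).

        For each tree: permute one feature's column among that tree's OOB
        samples and record the increase in OOB MSE; the importance of a
        feature is the mean increase over all trees (trees that never split
        on the feature contribute zero).
        """
        self._check_fitted()
        imp = np.zeros(self.n_features_)
        for t, tree in enumerate(self.trees_):
            oob = np.flatnonzero(~self.inbag_[t])
            if oob.size == 0:
                continue
            buf = np.ascontiguousarray(self._X32[oob])
            y_oob = self._y[oob]
            base = tree.tree_.predict(buf).ravel()
            mse0 = float(np.mean((y_oob - base) ** 2))
            used = np.unique(tree.tree_.feature)
            used = used[used >= 0]
            for f in used:
                col = buf[:, f].copy()
                buf[:, f] = col[rng.permutation(oob.size)]
                pred = tree.tree_.predict(buf).ravel()
                imp[f] += float(np.mean((y_oob - pred) ** 2)) - mse0
                buf[:, f] = col
        return imp / self.n_trees
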