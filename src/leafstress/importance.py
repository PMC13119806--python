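"""Permutation-tested random-forest variable importance (%IncMSE).

Workflow mirrored from the R randomForest / rfPermute / rfUtilities stack
commonly used for trait-importance screening:

* a bagged regression forest (ntree = 500 by default, mtry = p/3) with
  explicit out-of-bag (OOB) bookkeeping;
* %IncMSE importance: permute one predictor's values within each tree's
  OOB samples, recompute the OOB error, and report the mean percentage
  increase over trees;
* per-predictor significance: the observed %IncMSE is compared against a
  null distribution from forests refit on response-permuted data
  (p = (1 + #{null >= observed}) / (n_perm + 1), so p is never exactly 0);
* whole-model significance: the OOB R^2 against its response-permutation
  null (99 permutations by convention);
* backward selection: iteratively drop the lowest-%IncMSE predictor and
  refit until a target predictor count remains.

The tree learner is scikit-learn's :class:`DecisionTreeRegressor`; the
bagging, OOB handling, permutation loops and selection logic live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from leafstress._rng import substream


@dataclass
class RandomForest:
    """A bagged regression forest with per-tree OOB index bookkeeping."""

    trees: list[DecisionTreeRegressor]
    bootstrap_indices: list[np.ndarray]
    oob_indices: list[np.ndarray]
    feature_names: tuple[str, ...]
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    oob_mse: float
    r_squared: float
    seed: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)


@dataclass
class ImportanceResult:
    """Per-predictor %IncMSE with optional permutation p-values."""

    inc_mse: pd.Series
    p_values: pd.Series | None
    r_squared: float
    model_p: float | None
    n_trees: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"inc_mse": self.inc_mse})
        if self.p_values is not None:
            out["p"] = self.p_values
        return out.sort_values("inc_mse", ascending=False)


def _as_matrix(matrix: pd.DataFrame, response: str | None = None):
    if response is not None:
        y = matrix[response].to_numpy(dtype=float)
        X = matrix.drop(columns=[response])
    else:
        raise ValueError("response column must be named")
    return X, y


def fit_forest(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    n_trees: int = 500,
    seed: int = 0,
    max_features: float | str | None = None,
    min_obs: int = 10,
) -> RandomForest:
    """Fit a bagged regression forest with OOB error tracking.

    ``max_features`` defaults to the regression-forest one-third-of-
    predictors convention, rounded up so small predictor sets are not
    reduced to single-feature splits.  OOB R^2 = 1 - OOB-MSE / var(y); it
    can be negative (e.g. for a constant or unpredictable response).
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < min_obs:
        raise ValueError(f"need at least {min_obs} observations, got {n}")
    if max_features is None:
        max_features = max(-(-p // 3), 1)
    rng = substream(seed, "forest")
    Xm = X.to_numpy(dtype=float)

    trees, boots, oobs = [], [], []
    all_idx = np.arange(n)
    oob_sum = np.zeros(n)
    oob_count = np.zeros(n)
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(all_idx, boot, assume_unique=False)
        tree = DecisionTreeRegressor(
            max_features=max_features, random_state=int(rng.integers(2**31))
        )
        tree.fit(Xm[boot], y[boot])
        if oob.size:
            pred = tree.predict(Xm[oob])
            oob_sum[oob] += pred
            oob_count[oob] += 1
        trees.append(tree)
        boots.append(boot)
        oobs.append(oob)

    covered = oob_count > 0
    if not covered.any():
        raise ValueError("no out-of-bag samples; increase n_trees")
    oob_pred = oob_sum[covered] / oob_count[covered]
    oob_mse = float(np.mean((y[covered] - oob_pred) ** 2))
    var_y = float(np.var(y))
    r2 = 1.0 - oob_mse / var_y if var_y > 0 else -np.inf
    return RandomForest(
        trees=trees,
        bootstrap_indices=boots,
        oob_indices=oobs,
        feature_names=tuple(X.columns),
        X=Xm,
        y=y,
        oob_mse=oob_mse,
        r_squared=r2,
        seed=seed,
    )


def permutation_importance(forest: RandomForest, seed: int | None = None) -> pd.Series:
    """%IncMSE per predictor via tree-wise OOB permutation.

    For each tree and predictor, the predictor's values are shuffled
    within the tree's OOB samples and the OOB MSE recomputed; the
    importance is the mean MSE increase over trees, expressed as a
    percentage of the mean per-tree OOB MSE.  A predictor the forest
    never uses scores ~0; values can be slightly negative by chance.
    """
    rng = substream(forest.seed if seed is None else seed, "perm_importance")
    p = len(forest.feature_names)
    increases = np.zeros(p)
    base_total = 0.0
    n_used = 0
    for tree, oob in zip(forest.trees, forest.oob_indices):
        if oob.size < 2:
            continue
        X_oob = forest.X[oob]
        y_oob = forest.y[oob]
        base_mse = float(np.mean((y_oob - tree.predict(X_oob)) ** 2))
        base_total += base_mse
        n_used += 1
        for j in range(p):
            perm = rng.permutation(oob.size)
            X_perm = X_oob.copy()
            X_perm[:, j] = X_oob[perm, j]
            perm_mse = float(np.mean((y_oob - tree.predict(X_perm)) ** 2))
            increases[j] += perm_mse - base_mse
    if n_used == 0:
        raise ValueError("no usable OOB samples for importance")
    mean_base = base_total / n_used
    if mean_base == 0.0:
        return pd.Series(np.zeros(p), index=forest.feature_names, name="inc_mse")
    inc = 100.0 * (increases / n_used) / mean_base
    return pd.Series(inc, index=forest.feature_names, name="inc_mse")


def importance_significance(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    n_perm: int = 100,
    n_trees: int = 500,
    seed: int = 0,
) -> ImportanceResult:
    """Per-predictor permutation test of %IncMSE.

    The null distribution refits the forest ``n_perm`` times on a
    response-permuted copy of the data; p = (1 + #{null >= observed}) /
    (n_perm + 1), bounded below by 1/(n_perm+1).
    """
    if n_perm < 20:
        raise ValueError("need at least 20 permutations for a usable p-value")
    y = np.asarray(y, dtype=float)
    forest = fit_forest(X, y, n_trees=n_trees, seed=seed)
    observed = permutation_importance(forest)
    rng = substream(seed, "importance_null")
    exceed = np.zeros(len(observed))
    for b in range(n_perm):
        y_null = rng.permutation(y)
        null_forest = fit_forest(
            X, y_null, n_trees=n_trees, seed=int(rng.integers(2**31))
        )
        null_imp = permutation_importance(null_forest)
        exceed += (null_imp.to_numpy() >= observed.to_numpy()).astype(float)
    p_values = pd.Series(
        (1.0 + exceed) / (n_perm + 1.0), index=observed.index, name="p"
    )
    return ImportanceResult(
        inc_mse=observed,
        p_values=p_values,
        r_squared=forest.r_squared,
        model_p=None,
        n_trees=n_trees,
        seed=seed,
    )


def model_significance(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    n_perm: int = 99,
    n_trees: int = 500,
    seed: int = 0,
) -> tuple[float, float]:
    """Whole-model permutation test: (OOB R^2, p).

    The null distribution is the OOB R^2 of forests refit on permuted
    responses; with 99 permutations the attainable minimum p is 0.01.
    """
    y = np.asarray(y, dtype=float)
    forest = fit_forest(X, y, n_trees=n_trees, seed=seed)
    rng = substream(seed, "model_null")
    exceed = 0
    for _ in range(n_perm):
        y_null = rng.permutation(y)
        null_forest = fit_forest(
            X, y_null, n_trees=n_trees, seed=int(rng.integers(2**31))
        )
        if null_forest.r_squared >= forest.r_squared:
            exceed += 1
    p = (1.0 + exceed) / (n_perm + 1.0)
    return forest.r_squared, p


def backward_select(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    target_count: int = 14,
    n_trees: int = 500,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Backward variable selection by lowest %IncMSE.

    Refits the forest after each drop until ``target_count`` predictors
    remain.  Returns (reduced matrix, drop order).  Deterministic for a
    fixed seed.
    """
    X = pd.DataFrame(X)
    if target_count > X.shape[1]:
        raise ValueError("target_count exceeds the number of candidate predictors")
    if target_count < 1:
        raise ValueError("target_count must be positive")
    dropped: list[str] = []
    current = X
    step = 0
    while current.shape[1] > target_count:
        forest = fit_forest(current, y, n_trees=n_trees, seed=seed + step)
        imp = permutation_importance(forest)
        worst = imp.idxmin()
        dropped.append(str(worst))
        current = current.drop(columns=[worst])
        step += 1
    return current, dropped
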