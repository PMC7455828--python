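"""Random-forest gene selection with OOB-based hyperparameter tuning.

The forest is explicit bagging over CART trees (Gini splits): each tree is
fitted to a bootstrap resample, expressed as per-sample bootstrap counts, and
predictions for the samples a tree did not see (out-of-bag, OOB) provide an
internal error estimate. Keeping the bootstrap bookkeeping in the open gives
three things the selection procedure needs:

* a cumulative OOB error trace as trees are added (for choosing ntree by
  "lowest error and stability"),
* MeanDecreaseGini on the raw total-impurity-decrease scale (node counts
  times Gini decrease, summed over splits, averaged over trees) so an
  absolute importance threshold is meaningful,
* MeanDecreaseAccuracy as true per-tree OOB permutation importance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .datatypes import DataError


@dataclass
class _Forest:
    trees: list
    oob_masks: np.ndarray  # n_trees x n_samples, True where sample is OOB
    classes: np.ndarray


@dataclass
class RfSelection:
    """Tuned forest parameters, per-gene importances, and the selected genes."""

    mtry_sweep: list[tuple[int, float]]
    ntree_sweep: list[tuple[int, float]]
    chosen_mtry: int
    chosen_ntree: int
    importance: pd.DataFrame  # columns: mean_decrease_accuracy, mean_decrease_gini
    selected_genes: list[str]
    gini_threshold: float


def _validate_xy(X, y):
    X = pd.DataFrame(X)
    y = pd.Series(np.asarray(y), index=X.index)
    classes = np.unique(y)
    if len(classes) < 2:
        raise DataError("both classes must be present")
    if len(classes) > 2:
        raise DataError("two-class labels expected")
    return X, y.to_numpy(), classes


def _fit_forest(X: np.ndarray, y_enc: np.ndarray, n_trees: int, mtry: int, seed) -> _Forest:
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    trees, oob = [], np.zeros((n_trees, n), dtype=bool)
    tree_seeds = rng.integers(0, 2**31 - 1, size=n_trees)
    for i in range(n_trees):
        idx = rng.integers(0, n, size=n)
        counts = np.bincount(idx, minlength=n).astype(float)
        tree = DecisionTreeClassifier(
            criterion="gini", max_features=mtry, random_state=int(tree_seeds[i])
        )
        tree.fit(X, y_enc, sample_weight=counts)
        trees.append(tree)
        oob[i] = counts == 0
    return _Forest(trees=trees, oob_masks=oob, classes=np.array([0, 1]))


def _oob_votes(forest: _Forest, X: np.ndarray) -> np.ndarray:
    """Per-tree OOB class predictions stacked into cumulative vote counts."""
    n = X.shape[0]
    votes = np.zeros((len(forest.trees), n, 2), dtype=np.int32)
    for i, (tree, mask) in enumerate(zip(forest.trees, forest.oob_masks)):
        if mask.any():
            pred = tree.predict(X[mask]).astype(int)
            votes[i, np.flatnonzero(mask), pred] = 1
    return votes


def _oob_error_trace(forest: _Forest, X: np.ndarray, y_enc: np.ndarray) -> np.ndarray:
    """OOB misclassification rate after 1..n_trees trees (majority vote,
    samples with no OOB vote yet excluded)."""
    votes = np.cumsum(_oob_votes(forest, X), axis=0)
    voted = votes.sum(axis=2) > 0
    pred = (votes[:, :, 1] > votes[:, :, 0]).astype(int)
    ties = votes[:, :, 1] == votes[:, :, 0]
    pred[ties] = 0  # deterministic tie-break: first class
    errs = np.empty(len(forest.trees))
    for t in range(len(forest.trees)):
        m = voted[t]
        errs[t] = np.mean(pred[t, m] != y_enc[m]) if m.any() else np.nan
    return errs


def oob_error(forest: _Forest, X: np.ndarray, y_enc: np.ndarray) -> float:
    return float(_oob_error_trace(forest, X, y_enc)[-1])


def tune_mtry(
    X, y, mtry_max: int = 2000, ntree_probe: int = 500, seed: int = 0
) -> tuple[list[tuple[int, float]], int]:
    """Loop mtry = 1..min(mtry_max, n_genes), recording OOB error of a probe
    forest for each; returns (sweep, argmin mtry, ties to the smallest)."""
    Xdf, y_arr, classes = _validate_xy(X, y)
    y_enc = (y_arr == classes[0]).astype(int)  # classes sorted; 'case' < 'control'
    Xv = Xdf.to_numpy(dtype=float)
    p = Xv.shape[1]
    sweep = []
    for mtry in range(1, min(mtry_max, p) + 1):
        forest = _fit_forest(Xv, y_enc, ntree_probe, mtry, np.random.SeedSequence([seed, mtry]))
        sweep.append((mtry, oob_error(forest, Xv, y_enc)))
    errs = np.array([e for _, e in sweep])
    chosen = sweep[int(np.argmin(errs))][0]  # np.argmin returns first minimum
    return sweep, chosen


def tune_ntree(
    X,
    y,
    chosen_mtry: int,
    ntree_max: int = 3000,
    stability_eps: float = 0.005,
    seed: int = 0,
) -> tuple[list[tuple[int, float]], int]:
    """Trace cumulative OOB error up to ``ntree_max`` trees; chosen_ntree is
    the smallest t from which the error stays within ``stability_eps`` of the
    overall minimum (lowest error with stability)."""
    Xdf, y_arr, classes = _validate_xy(X, y)
    y_enc = (y_arr == classes[0]).astype(int)
    Xv = Xdf.to_numpy(dtype=float)
    forest = _fit_forest(Xv, y_enc, ntree_max, chosen_mtry, np.random.SeedSequence([seed, 0]))
    trace = _oob_error_trace(forest, Xv, y_enc)
    finite = np.where(np.isnan(trace), np.inf, trace)
    min_err = finite.min()
    within = finite <= min_err + stability_eps
    # smallest t such that all later errors stay inside the band
    stable_from = len(within)
    for t in range(len(within) - 1, -1, -1):
        if within[t]:
            stable_from = t
        else:
            break
    if stable_from >= len(within):  # trace never settles inside the band: fall back to argmin
        stable_from = int(np.argmin(finite))
    chosen = stable_from + 1  # 1-based tree count
    sweep = [(t + 1, float(trace[t])) for t in range(len(trace))]
    return sweep, chosen


def _raw_gini_importance(forest: _Forest, p: int) -> np.ndarray:
    acc = np.zeros(p)
    for tree in forest.trees:
        t = tree.tree_
        left, right = t.children_left, t.children_right
        internal = left != -1
        w, imp = t.weighted_n_node_samples, t.impurity
        decrease = (w * imp)[internal] - (w * imp)[left[internal]] - (w * imp)[right[internal]]
        np.add.at(acc, t.feature[internal], decrease)
    return acc / len(forest.trees)


def _permutation_importance(
    forest: _Forest, X: np.ndarray, y_enc: np.ndarray, seed, chunk: int = 64
) -> np.ndarray:
    """Mean over trees of the drop in that tree's OOB accuracy when one
    feature's OOB values are permuted."""
    rng = np.random.default_rng(seed)
    n, p = X.shape
    total = np.zeros(p)
    used = 0
    for tree, mask in zip(forest.trees, forest.oob_masks):
        m = int(mask.sum())
        if m == 0:
            continue
        used += 1
        Xo = X[mask]
        yo = y_enc[mask]
        base = (tree.predict(Xo).astype(int) == yo).mean()
        for start in range(0, p, chunk):
            feats = range(start, min(start + chunk, p))
            block = np.repeat(Xo[None, :, :], len(feats), axis=0)
            for bi, j in enumerate(feats):
                block[bi, :, j] = Xo[rng.permutation(m), j]
            preds = tree.predict(block.reshape(-1, p)).astype(int).reshape(len(feats), m)
            total[list(feats)] += base - (preds == yo).mean(axis=1)
    return total / max(used, 1)


def importance_and_select(
    X,
    y,
    chosen_mtry: int,
    chosen_ntree: int,
    gini_threshold: float = 0.15,
    seed: int = 0,
    normalize_importance: bool = False,
    mtry_sweep: list | None = None,
    ntree_sweep: list | None = None,
) -> RfSelection:
    """Fit the tuned forest, compute both importance measures, and select the
    genes whose MeanDecreaseGini reaches ``gini_threshold`` (descending order).

    An empty selection is reported with a warning, not an exception.
    ``normalize_importance`` rescales Gini importances to sum to one instead
    of the raw total-decrease scale.
    """
    Xdf, y_arr, classes = _validate_xy(X, y)
    y_enc = (y_arr == classes[0]).astype(int)
    Xv = Xdf.to_numpy(dtype=float)
    forest = _fit_forest(Xv, y_enc, chosen_ntree, chosen_mtry, np.random.SeedSequence([seed, 1]))
    gini = _raw_gini_importance(forest, Xv.shape[1])
    if normalize_importance and gini.sum() > 0:
        gini = gini / gini.sum()
    mda = _permutation_importance(forest, Xv, y_enc, np.random.SeedSequence([seed, 2]))
    importance = pd.DataFrame(
        {"mean_decrease_accuracy": mda, "mean_decrease_gini": gini}, index=Xdf.columns
    )
    ranked = importance.sort_values("mean_decrease_gini", ascending=False)
    selected = list(ranked.index[ranked["mean_decrease_gini"] >= gini_threshold])
    if not selected:
        warnings.warn("gini_threshold selects no genes; returning empty selection")
    return RfSelection(
        mtry_sweep=mtry_sweep or [],
        ntree_sweep=ntree_sweep or [],
        chosen_mtry=chosen_mtry,
        chosen_ntree=chosen_ntree,
        importance=importance,
        selected_genes=selected,
        gini_threshold=gini_threshold,
    )


def select_genes(
    X,
    y,
    mtry_max: int = 2000,
    ntree_probe: int = 500,
    ntree_max: int = 3000,
    stability_eps: float = 0.005,
    gini_threshold: float = 0.15,
    seed: int = 0,
    importance_min_trees: int = 500,
) -> RfSelection:
    """Full tuning + selection convenience wrapper.

    On strongly separable data the stability rule can settle on a very small
    ntree (the error trace hits its minimum immediately); importance averages
    over so few trees are unstable, so the forest used for importance gets at
    least ``importance_min_trees`` trees while ``chosen_ntree`` still records
    the tuned value.
    """
    mtry_sweep, chosen_mtry = tune_mtry(X, y, mtry_max=mtry_max, ntree_probe=ntree_probe, seed=seed)
    ntree_sweep, chosen_ntree = tune_ntree(
        X, y, chosen_mtry, ntree_max=ntree_max, stability_eps=stability_eps, seed=seed
    )
    sel = importance_and_select(
        X,
        y,
        chosen_mtry,
        max(chosen_ntree, importance_min_trees),
        gini_threshold=gini_threshold,
        seed=seed,
        mtry_sweep=mtry_sweep,
        ntree_sweep=ntree_sweep,
    )
    sel.chosen_ntree = chosen_ntree
    return sel
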