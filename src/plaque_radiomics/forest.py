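"""Random forest of shallow classification trees, implemented natively.

Ten bootstrap-sampled binary trees of maximum depth 3 (root plus two
internal levels, at most eight leaves), Gini-impurity splits over a random
ceil(sqrt(d))-sized feature subset per node, and class-1 leaf probabilities
averaged across trees.  The implementation is deliberately self-contained so
tree structure is inspectable, ties are broken reproducibly (lowest feature
index, then lowest threshold) and seeded results are portable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["ForestConfig", "TreeNode", "ForestModel", "fit_forest", "predict_proba"]


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 10
    max_depth: int = 3
    min_leaf: int = 2
    vote_mode: str = "probability"  # or "vote": hard 0/1 per tree
    seed: int = 0


@dataclass
class TreeNode:
    """One node: either a split (feature index + threshold) or a leaf."""

    prob: float  # class-1 probability of the training samples in this node
    feature: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None  # feature value <= threshold
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"prob": self.prob}
        return {
            "prob": self.prob,
            "feature": self.feature,
            "threshold": self.threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }


@dataclass
class ForestModel:
    trees: List[TreeNode]
    feature_names: List[str]
    config: ForestConfig

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": self.feature_names,
                "config": self.config.__dict__,
                "trees": [t.to_dict() for t in self.trees],
            }
        )


def _best_split(X: np.ndarray, y: np.ndarray, feat_subset: np.ndarray, min_leaf: int):
    """Best Gini split over the given features.

    Ties broken by lowest feature index, then lowest threshold; a split must
    leave at least ``min_leaf`` samples on each side.  Returns
    (feature, threshold, left_mask) or None.
    """
    n = y.size
    best = None
    best_impurity = np.inf
    for f in np.sort(feat_subset):
        x = X[:, f]
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        # Candidate cut positions: between distinct consecutive values.
        cum_pos = np.cumsum(ys)
        total_pos = cum_pos[-1]
        for cut in range(min_leaf, n - min_leaf + 1):
            if xs[cut - 1] == xs[cut]:
                continue
            n_l = cut
            n_r = n - cut
            pos_l = cum_pos[cut - 1]
            pos_r = total_pos - pos_l
            p_l = pos_l / n_l
            p_r = pos_r / n_r
            imp = (n_l * 2 * p_l * (1 - p_l) + n_r * 2 * p_r * (1 - p_r)) / n
            if imp < best_impurity - 1e-15:
                thr = 0.5 * (xs[cut - 1] + xs[cut])
                best_impurity = imp
                best = (int(f), float(thr))
    if best is None:
        return None
    f, thr = best
    return f, thr, X[:, f] <= thr


def _node_subset(
    feature_names: Sequence[str], k: int, seed: int, tree_idx: int, path: str
) -> np.ndarray:
    """Pseudorandom feature subset keyed by (seed, tree, node path, name).

    Hash-derived priorities make the draw deterministic and portable, and
    give identical priorities to shared features across models that differ
    only in their feature list (a common-random-numbers scheme: model
    comparisons then reflect the feature sets, not sampling noise).
    """
    prios = []
    for j, name in enumerate(feature_names):
        digest = hashlib.blake2b(
            f"{seed}|{tree_idx}|{path}|{name}".encode(), digest_size=8
        ).digest()
        prios.append((int.from_bytes(digest, "big"), j))
    prios.sort()
    return np.array(sorted(j for _, j in prios[:k]))


def _grow(
    X: np.ndarray,
    y: np.ndarray,
    depth: int,
    config: ForestConfig,
    names: Sequence[str],
    tree_idx: int,
    path: str,
    n_sub: int,
) -> TreeNode:
    node = TreeNode(prob=float(y.mean()))
    if depth >= config.max_depth or y.size < 2 * config.min_leaf or len(np.unique(y)) == 1:
        return node
    subset = _node_subset(names, n_sub, config.seed, tree_idx, path)
    split = _best_split(X, y, subset, config.min_leaf)
    if split is None:
        return node
    f, thr, left_mask = split
    node.feature = f
    node.threshold = thr
    node.left = _grow(
        X[left_mask], y[left_mask], depth + 1, config, names, tree_idx, path + "L", n_sub
    )
    node.right = _grow(
        X[~left_mask], y[~left_mask], depth + 1, config, names, tree_idx, path + "R", n_sub
    )
    return node


def fit_forest(
    features: pd.DataFrame,
    labels,
    config: ForestConfig = ForestConfig(),
) -> ForestModel:
    """Train the bootstrap ensemble; deterministic given the config seed."""
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if features.shape[1] < 1:
        raise ValueError("at least one feature required")
    X = features.to_numpy(dtype=float)
    n, d = X.shape
    n_sub = int(np.ceil(np.sqrt(d)))
    rng = np.random.default_rng(config.seed)
    names = [str(c) for c in features.columns]
    trees = []
    for t in range(config.n_trees):
        idx = rng.integers(0, n, size=n)
        trees.append(_grow(X[idx], y[idx], 0, config, names, t, "", n_sub))
    return ForestModel(trees=trees, feature_names=names, config=config)


def oob_scores(
    features: pd.DataFrame, labels, config: ForestConfig = ForestConfig()
) -> np.ndarray:
    """Out-of-bag class-1 scores: each patient is scored only by the trees
    whose bootstrap sample excluded them.

    Refits the forest with the same seed (so the trees equal
    :func:`fit_forest`'s) while tracking bag membership.  Patients that are
    in every bag receive NaN.
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    X = features.to_numpy(dtype=float)
    n, d = X.shape
    n_sub = int(np.ceil(np.sqrt(d)))
    rng = np.random.default_rng(config.seed)
    names = [str(c) for c in features.columns]
    votes = np.zeros(n)
    counts = np.zeros(n)
    for t in range(config.n_trees):
        idx = rng.integers(0, n, size=n)
        tree = _grow(X[idx], y[idx], 0, config, names, t, "", n_sub)
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size == 0:
            continue
        preds = _tree_predict(tree, X[oob])
        if config.vote_mode == "vote":
            preds = (preds > 0.5).astype(float)
        votes[oob] += preds
        counts[oob] += 1
    out = np.full(n, np.nan)
    seen = counts > 0
    out[seen] = votes[seen] / counts[seen]
    return out


def _tree_predict(node: TreeNode, X: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0])
    stack = [(node, np.arange(X.shape[0]))]
    while stack:
        nd, idx = stack.pop()
        if nd.is_leaf:
            out[idx] = nd.prob
            continue
        left = X[idx, nd.feature] <= nd.threshold
        stack.append((nd.left, idx[left]))
        stack.append((nd.right, idx[~left]))
    return out


def predict_proba(model: ForestModel, features: pd.DataFrame) -> np.ndarray:
    """Mean per-tree class-1 probability (or mean hard vote in vote mode)."""
    missing = [f for f in model.feature_names if f not in features.columns]
    if missing:
        raise KeyError(f"missing features: {missing}")
    X = features[model.feature_names].to_numpy(dtype=float)
    preds = np.stack([_tree_predict(t, X) for t in model.trees])
    if model.config.vote_mode == "vote":
        preds = (preds > 0.5).astype(float)
    return preds.mean(axis=0)
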