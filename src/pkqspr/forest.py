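"""Balanced forest of recursive-partitioning (CART-style) classification trees.

The class schemes are heavily imbalanced (roughly half of all compounds have
V_ss above 1 L/kg and most have low fraction unbound), so each tree is grown
on a *balanced bootstrap*: sampling with replacement separately per class,
exactly k members from each, where k is the size of the smallest class.  The
forest is deliberately small (default 10 trees).  Splits minimize Gini
impurity over a random draw of mtry = floor(sqrt(p)) candidate descriptors
per node; every candidacy and selection is logged so that the
percent-selection-frequency importance (share of split opportunities at which
an eligible descriptor was chosen) can be reported.

Prediction uses an unweighted majority vote of the trees; class probabilities
(needed for the Hand–Till multiclass AUC) are the mean of per-tree leaf class
frequencies.  Out-of-bag statistics aggregate, for each training compound,
only the trees whose bootstrap excluded it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DecisionTree",
    "ForestModel",
    "balanced_bootstrap",
    "fit_tree",
    "fit_balanced_forest",
    "predict_forest",
    "oob_predictions",
    "selection_frequency_importance",
]

MIN_LEAF_DEFAULT = 5


def balanced_bootstrap(labels: Sequence, seed: int) -> np.ndarray:
    """Per-class bootstrap with exactly min-class-size draws from each class.

    Returns in-bag indices (with repeats).  Deterministic under ``seed``.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts == 0):
        raise ValueError("empty class")
    k = int(counts.min())
    rng = np.random.default_rng(seed)
    parts = []
    for cls in classes:
        members = np.where(labels == cls)[0]
        parts.append(rng.choice(members, size=k, replace=True))
    return np.concatenate(parts)


@dataclass
class _Node:
    feature: int = -1  # -1 marks a leaf
    threshold: float = np.nan
    left: "_Node | None" = None
    right: "_Node | None" = None
    counts: np.ndarray | None = None  # per-class counts of in-bag sample at node

    @property
    def is_leaf(self) -> bool:
        return self.feature < 0

    def to_dict(self) -> dict:
        d = {"counts": self.counts.tolist()}
        if not self.is_leaf:
            d.update(
                feature=int(self.feature),
                threshold=float(self.threshold),
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "_Node":
        node = cls(counts=np.asarray(d["counts"], dtype=float))
        if "feature" in d:
            node.feature = d["feature"]
            node.threshold = d["threshold"]
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


@dataclass
class DecisionTree:
    root: _Node
    classes: np.ndarray
    in_bag: np.ndarray  # in-bag training indices (with repeats)
    candidate_log: list[tuple[tuple[int, ...], int]] = field(default_factory=list)
    # each entry: (eligible descriptor indices at a realized split, selected index)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.zeros((X.shape[0], len(self.classes)))
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out[i] = node.counts / node.counts.sum()
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes[np.argmax(proba, axis=1)]


def _gini_best_split(Xcol: np.ndarray, y_codes: np.ndarray, n_classes: int, min_child: int = 1):
    """Best (threshold, impurity) for one feature by exhaustive midpoint scan.

    Returns (threshold, weighted_gini) or None if the column admits no split.
    Thresholds are midpoints between consecutive distinct sorted values; ties
    in impurity are broken toward the lowest threshold.
    """
    order = np.argsort(Xcol, kind="stable")
    xs = Xcol[order]
    ys = y_codes[order]
    n = xs.size
    # one-hot prefix counts
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), ys] = 1.0
    prefix = np.cumsum(onehot, axis=0)
    total = prefix[-1]
    # candidate cut after position i (0-based): left = 0..i
    distinct = np.where(np.diff(xs) > 0)[0]
    if distinct.size == 0:
        return None
    valid = distinct[(distinct + 1 >= min_child) & (n - distinct - 1 >= min_child)]
    if valid.size == 0:
        return None
    nl = (valid + 1).astype(float)
    nr = n - nl
    left_counts = prefix[valid]
    right_counts = total - left_counts
    gini_l = 1.0 - np.sum((left_counts / nl[:, None]) ** 2, axis=1)
    gini_r = 1.0 - np.sum((right_counts / nr[:, None]) ** 2, axis=1)
    weighted = (nl * gini_l + nr * gini_r) / n
    best = int(np.argmin(weighted))  # argmin takes first minimum -> lowest threshold
    thr = 0.5 * (xs[valid[best]] + xs[valid[best] + 1])
    return float(thr), float(weighted[best])


def fit_tree(
    X: np.ndarray,
    labels: Sequence,
    in_bag: np.ndarray,
    mtry: int,
    seed: int,
    min_leaf: int = MIN_LEAF_DEFAULT,
    classes: np.ndarray | None = None,
) -> DecisionTree:
    """Grow one CART-style tree on the in-bag sample.

    At each node ``mtry`` candidate descriptors are drawn without replacement;
    the (descriptor, threshold) pair minimizing weighted Gini impurity is
    chosen, ties broken by lowest descriptor index then lowest threshold.
    Nodes stop splitting when pure, smaller than ``min_leaf``, or when no
    candidate admits a valid split.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    if mtry > X.shape[1]:
        raise ValueError("mtry exceeds number of descriptors")
    code_of = {c: i for i, c in enumerate(classes)}
    y_codes = np.array([code_of[l] for l in labels])
    rng = np.random.default_rng(seed)
    in_bag = np.asarray(in_bag, dtype=int)
    log: list[tuple[tuple[int, ...], int]] = []
    n_classes = len(classes)

    def build(idx: np.ndarray) -> _Node:
        counts = np.bincount(y_codes[idx], minlength=n_classes).astype(float)
        node = _Node(counts=counts)
        if idx.size < min_leaf or np.count_nonzero(counts) <= 1:
            return node
        candidates = np.sort(rng.choice(X.shape[1], size=mtry, replace=False))
        best = None  # (gini, feature, threshold)
        for f in candidates:
            res = _gini_best_split(X[idx, f], y_codes[idx], n_classes)
            if res is None:
                continue
            thr, g = res
            if best is None or g < best[0] - 1e-15 or (
                abs(g - best[0]) <= 1e-15 and (f < best[1] or (f == best[1] and thr < best[2]))
            ):
                best = (g, int(f), thr)
        if best is None:
            return node
        _, f, thr = best
        log.append((tuple(int(c) for c in candidates), f))
        node.feature, node.threshold = f, thr
        mask = X[idx, f] <= thr
        node.left = build(idx[mask])
        node.right = build(idx[~mask])
        return node

    root = build(in_bag)
    return DecisionTree(root=root, classes=classes, in_bag=in_bag, candidate_log=log)


@dataclass
class ForestModel:
    trees: list[DecisionTree]
    classes: np.ndarray
    tree_seeds: list[int]
    n_train: int
    variable_names: list[str] = field(default_factory=list)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probas = [t.predict_proba(X) for t in self.trees]
        return np.mean(probas, axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Unweighted majority vote; ties go to the lowest class label."""
        votes = np.stack([t.predict(X) for t in self.trees])  # (n_trees, n)
        out = []
        for col in votes.T:
            vals, counts = np.unique(col, return_counts=True)
            out.append(vals[np.argmax(counts)])
        return np.asarray(out)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": self.classes.tolist(),
            "tree_seeds": self.tree_seeds,
            "n_train": self.n_train,
            "variable_names": self.variable_names,
            "trees": [
                {
                    "root": t.root.to_dict(),
                    "in_bag": t.in_bag.tolist(),
                    "candidate_log": [[list(c), s] for c, s in t.candidate_log],
                }
                for t in self.trees
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ForestModel":
        d = json.loads(Path(path).read_text())
        classes = np.asarray(d["classes"])
        trees = [
            DecisionTree(
                root=_Node.from_dict(t["root"]),
                classes=classes,
                in_bag=np.asarray(t["in_bag"], dtype=int),
                candidate_log=[(tuple(c), s) for c, s in t["candidate_log"]],
            )
            for t in d["trees"]
        ]
        return cls(
            trees=trees,
            classes=classes,
            tree_seeds=d["tree_seeds"],
            n_train=d["n_train"],
            variable_names=d.get("variable_names", []),
        )


def fit_balanced_forest(
    X: np.ndarray,
    labels: Sequence,
    n_trees: int = 10,
    seed: int = 0,
    mtry: int | None = None,
    min_leaf: int = MIN_LEAF_DEFAULT,
    variable_names: Sequence[str] | None = None,
) -> ForestModel:
    """Fit a balanced forest: each tree on its own balanced bootstrap."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if mtry is None:
        mtry = max(1, int(np.floor(np.sqrt(X.shape[1]))))
    ss = np.random.SeedSequence(seed)
    tree_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * n_trees)]
    trees = []
    for i in range(n_trees):
        bag = balanced_bootstrap(labels, seed=tree_seeds[2 * i])
        trees.append(
            fit_tree(X, labels, bag, mtry=mtry, seed=tree_seeds[2 * i + 1], min_leaf=min_leaf, classes=classes)
        )
    return ForestModel(
        trees=trees,
        classes=classes,
        tree_seeds=tree_seeds,
        n_train=X.shape[0],
        variable_names=list(variable_names) if variable_names else [f"x{j}" for j in range(X.shape[1])],
    )


def predict_forest(model: ForestModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: (majority-vote classes, mean leaf-frequency probabilities)."""
    return model.predict(X), model.predict_proba(X)


def oob_predictions(model: ForestModel, X: np.ndarray, labels: Sequence | None = None) -> dict:
    """Out-of-bag class predictions and vote fractions for the training matrix.

    A compound's OOB prediction aggregates only trees whose bootstrap excluded
    it.  Compounds in-bag in every tree are flagged and carry NaN scores.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    K = len(model.classes)
    proba_sum = np.zeros((n, K))
    vote_counts = np.zeros((n, K))
    n_oob_trees = np.zeros(n, dtype=int)
    for tree in model.trees:
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[np.unique(tree.in_bag)] = False
        if not oob_mask.any():
            continue
        idx = np.where(oob_mask)[0]
        proba = tree.predict_proba(X[idx])
        proba_sum[idx] += proba
        pred_codes = np.argmax(proba, axis=1)
        vote_counts[idx, pred_codes] += 1
        n_oob_trees[idx] += 1
    covered = n_oob_trees > 0
    proba = np.full((n, K), np.nan)
    proba[covered] = proba_sum[covered] / n_oob_trees[covered, None]
    vote_frac = np.full((n, K), np.nan)
    vote_frac[covered] = vote_counts[covered] / n_oob_trees[covered, None]
    pred = np.full(n, None, dtype=object)
    pred[covered] = model.classes[np.argmax(vote_counts[covered], axis=1)]
    out = {
        "prediction": pred,
        "proba": proba,
        "vote_fractions": vote_frac,
        "n_oob_trees": n_oob_trees,
        "covered": covered,
        "classes": model.classes,
    }
    if labels is not None:
        labels = np.asarray(labels)
        out["accuracy"] = float(np.mean(pred[covered] == labels[covered])) if covered.any() else np.nan
    return out


def selection_frequency_importance(model: ForestModel) -> pd.DataFrame:
    """Percent-selection-frequency importance table.

    For each descriptor: ``number_of_chances`` = nodes (across all trees)
    where it was among the eligible candidates at a realized split;
    ``percent_selection_frequency`` = 100 x selections / chances.  Descriptors
    never eligible are reported with NaN frequency (not assessed).
    """
    p = len(model.variable_names)
    chances = np.zeros(p, dtype=int)
    selections = np.zeros(p, dtype=int)
    for tree in model.trees:
        for eligible, selected in tree.candidate_log:
            for f in eligible:
                chances[f] += 1
            selections[selected] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(chances > 0, 100.0 * selections / np.maximum(chances, 1), np.nan)
    df = pd.DataFrame(
        {
            "descriptor": model.variable_names,
            "number_of_chances": chances,
            "selections": selections,
            "percent_selection_frequency": freq,
        }
    )
    return df.sort_values("percent_selection_frequency", ascending=False, na_position="last").reset_index(drop=True)
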