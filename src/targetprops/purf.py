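"""Weighted positive-unlabelled random forest with out-of-bag prediction.

The classifier at the package's core.  Trees are grown on uniform
bootstrap samples; class imbalance is handled by giving every positive
observation a configurable weight (unlabelled fixed at 1) inside the
weighted Gini split criterion and the leaf vote masses, while bootstrap
sampling stays uniform so OOB coverage is independent of the weight.

Unbiased predictions for training observations come from the out-of-bag
(OOB) scheme: an observation is predicted only by trees whose bootstrap
sample excluded it.  The fraction of a forest's votes for the positive
class is the observation's *positive similarity* — its drug-target
likeness score — thresholded at 0.5 for a class call.  Performance is
summarised by the G mean, the geometric mean of sensitivity and
specificity, which weights the two classes equally regardless of
imbalance.  A seed-shared grid search over mtry and the positive weight
pools OOB confusion counts over many forests and picks the combination
with the greatest pooled G mean.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RFConfig",
    "Tree",
    "RandomForestModel",
    "PUPrediction",
    "ConfusionCounts",
    "GridSearchResult",
    "train_forest",
    "oob_similarity",
    "full_similarity",
    "g_mean",
    "confusion_from_predictions",
    "permutation_importance",
    "classify",
    "grid_search",
    "similarity_histogram",
    "predictions_to_frame",
    "model_to_json",
    "model_from_json",
]


class TrainingError(ValueError):
    """Raised for untrainable inputs (single class, bad mtry, ...)."""


@dataclass(frozen=True)
class RFConfig:
    """Forest-growth parameters.

    ``positive_weight`` is the observation weight of the positive class
    (unlabelled held at 1); ``mtry`` the number of candidate features
    drawn at each node; ``min_node_size`` the smallest node that may
    still be split (1 = fully grown trees).
    """

    number_trees: int = 200
    mtry: int = 10
    positive_weight: float = 1.0
    seed: int = 0
    min_node_size: int = 1

    def __post_init__(self) -> None:
        if self.number_trees < 1:
            raise TrainingError("number_trees must be >= 1")
        if self.mtry < 1:
            raise TrainingError("mtry must be >= 1")
        if self.positive_weight <= 0:
            raise TrainingError("positive_weight must be > 0")
        if self.min_node_size < 1:
            raise TrainingError("min_node_size must be >= 1")


@dataclass
class Tree:
    """One axis-aligned binary decision tree in array form.

    ``feature[i] == -1`` marks a leaf; internal node *i* sends rows with
    ``x[feature[i]] <= threshold[i]`` to ``left[i]``, the rest to
    ``right[i]``.  Leaves store the summed training weight of each class.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    weight_pos: np.ndarray
    weight_unl: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf index for every row of X."""
        node = np.zeros(X.shape[0], dtype=np.int64)
        active = self.feature[node] >= 0
        while active.any():
            idx = np.flatnonzero(active)
            nd = node[idx]
            goes_left = X[idx, self.feature[nd]] <= self.threshold[nd]
            node[idx] = np.where(goes_left, self.left[nd], self.right[nd])
            active = self.feature[node] >= 0
        return node

    def votes(self, X: np.ndarray) -> np.ndarray:
        """Per-row vote: 1 if the leaf's positive weight mass exceeds the
        unlabelled mass, else 0 (ties vote unlabelled)."""
        leaves = self.apply(X)
        return (self.weight_pos[leaves] > self.weight_unl[leaves]).astype(
            np.int8
        )


@dataclass
class RandomForestModel:
    """A trained forest with recorded per-tree bootstrap index sets."""

    trees: list[Tree]
    bootstrap_indices: list[np.ndarray]
    config: RFConfig
    n_train: int
    feature_names: list[str]


@dataclass
class PUPrediction:
    """Per-protein positive similarity and class call."""

    accession: str
    positive_similarity: float | None
    eligible_trees: int
    predicted_class: str  # "positive" / "unlabelled"
    mode: str  # "oob" / "full"

    @property
    def defined(self) -> bool:
        return self.eligible_trees >= 1


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            raise ValueError("no positive observations")
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            raise ValueError("no unlabelled observations")
        return self.tn / (self.tn + self.fp)

    @property
    def g_mean(self) -> float:
        return math.sqrt(self.sensitivity * self.specificity)


def g_mean(confusion: ConfusionCounts) -> float:
    """Geometric mean of sensitivity and specificity."""
    return confusion.g_mean


# ---------------------------------------------------------------------------
# Tree growing
# ---------------------------------------------------------------------------

def _best_split(X, y, w, rows, mtry, rng):
    """Best weighted-Gini split over a fresh random mtry feature subset.

    Returns (feature, threshold, left_rows, right_rows) or None.  Ties in
    impurity are broken toward the lowest feature index (features are
    scanned in ascending order and only strict improvements accepted) and
    the smallest split value (first candidate along the sorted axis).
    """
    n_features = X.shape[1]
    subset = rng.choice(n_features, size=mtry, replace=False)
    subset.sort()

    wr = w[rows]
    yr = y[rows]
    wtot = wr.sum()
    wpos_tot = float(wr[yr == 1].sum())
    wunl_tot = wtot - wpos_tot

    best = None
    best_impurity = np.inf
    for f in subset:
        x = X[rows, f]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        if xs[0] == xs[-1]:
            continue
        ws = wr[order]
        wp = np.where(yr[order] == 1, ws, 0.0)
        cum_w = np.cumsum(ws)[:-1]
        cum_p = np.cumsum(wp)[:-1]
        valid = xs[:-1] < xs[1:]
        if not valid.any():
            continue
        wl = cum_w[valid]
        pl = cum_p[valid]
        ul = wl - pl
        wr_ = wtot - wl
        pr = wpos_tot - pl
        ur = wunl_tot - ul
        gini_l = wl - (pl * pl + ul * ul) / wl
        gini_r = wr_ - (pr * pr + ur * ur) / wr_
        impurity = (gini_l + gini_r) / wtot
        k = int(np.argmin(impurity))
        if impurity[k] < best_impurity - 1e-12:
            best_impurity = impurity[k]
            cut_index = np.flatnonzero(valid)[k]
            threshold = 0.5 * (xs[cut_index] + xs[cut_index + 1])
            best = (int(f), float(threshold))
    if best is None:
        return None
    f, threshold = best
    go_left = X[rows, f] <= threshold
    return f, threshold, rows[go_left], rows[~go_left]


def _grow_tree(X, y, w, rows, mtry, min_node_size, rng) -> Tree:
    feature, threshold, left, right = [], [], [], []
    weight_pos, weight_unl = [], []

    def new_node():
        feature.append(-1)
        threshold.append(0.0)
        left.append(-1)
        right.append(-1)
        weight_pos.append(0.0)
        weight_unl.append(0.0)
        return len(feature) - 1

    stack = [(new_node(), rows)]
    while stack:
        node, node_rows = stack.pop()
        yr = y[node_rows]
        wp = float(w[node_rows][yr == 1].sum())
        wu = float(w[node_rows][yr == 0].sum())
        weight_pos[node] = wp
        weight_unl[node] = wu
        if (len(node_rows) <= min_node_size or wp == 0.0 or wu == 0.0):
            continue  # pure or too small: leaf
        split = _best_split(X, y, w, node_rows, mtry, rng)
        if split is None:
            continue
        f, thr, rows_l, rows_r = split
        feature[node] = f
        threshold[node] = thr
        node_l, node_r = new_node(), new_node()
        left[node] = node_l
        right[node] = node_r
        # Right pushed first so the left child is grown first (stable ids).
        stack.append((node_r, rows_r))
        stack.append((node_l, rows_l))
    return Tree(
        feature=np.asarray(feature, dtype=np.int64),
        threshold=np.asarray(threshold, dtype=np.float64),
        left=np.asarray(left, dtype=np.int64),
        right=np.asarray(right, dtype=np.int64),
        weight_pos=np.asarray(weight_pos, dtype=np.float64),
        weight_unl=np.asarray(weight_unl, dtype=np.float64),
    )


def _as_matrix(table) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=np.float64), [str(c) for c in
                                                  table.columns]
    arr = np.asarray(table, dtype=np.float64)
    return arr, [f"f{i}" for i in range(arr.shape[1])]


def train_forest(table, labels, config: RFConfig) -> RandomForestModel:
    """Grow a weighted PU random forest; fully seeded and reproducible.

    ``table`` is a DataFrame or 2-D array of features; ``labels`` a 0/1
    vector (1 = positive).  Each tree is grown on a uniform bootstrap
    sample of size n; positives carry ``config.positive_weight`` inside
    the split criterion and leaf masses.
    """
    X, names = _as_matrix(table)
    y = np.asarray(labels, dtype=np.int8)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise TrainingError("table and labels have mismatched shapes")
    if np.isnan(X).any():
        raise TrainingError("features contain missing values")
    if y.min() == y.max():
        raise TrainingError("training requires both classes present")
    if config.mtry > X.shape[1]:
        raise TrainingError(
            f"mtry={config.mtry} exceeds feature count {X.shape[1]}"
        )
    n = X.shape[0]
    w = np.where(y == 1, config.positive_weight, 1.0)
    rng = np.random.default_rng(config.seed)
    trees, boots = [], []
    for _ in range(config.number_trees):
        boot = rng.integers(0, n, size=n)
        trees.append(
            _grow_tree(X[boot], y[boot], w[boot], np.arange(n),
                       config.mtry, config.min_node_size, rng)
        )
        boots.append(boot)
    return RandomForestModel(
        trees=trees, bootstrap_indices=boots, config=config,
        n_train=n, feature_names=names,
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _accessions(table, n) -> list[str]:
    if isinstance(table, pd.DataFrame):
        return [str(a) for a in table.index]
    return [str(i) for i in range(n)]


def _similarity_predictions(accessions, pos_votes, eligible, mode,
                            positive_weight, cutoff=0.5):
    """Aggregate per-tree votes into weighted positive similarities.

    A tree's vote for the positive class carries the positive class
    weight; a vote for the unlabelled class carries weight 1.  The
    similarity is the positive fraction of the total weighted vote, so
    weighted positive votes + weighted unlabelled votes = total.
    """
    out = []
    for acc, p, e in zip(accessions, pos_votes, eligible):
        if e >= 1:
            weighted_pos = positive_weight * float(p)
            weighted_unl = float(e - p)
            sim = weighted_pos / (weighted_pos + weighted_unl)
            cls = "positive" if sim > cutoff else "unlabelled"
            out.append(PUPrediction(acc, sim, int(e), cls, mode))
        else:
            out.append(PUPrediction(acc, None, 0, "unlabelled", mode))
    return out


def oob_similarity(model: RandomForestModel, table) -> list[PUPrediction]:
    """Out-of-bag positive similarity for the training observations.

    ``table`` must contain exactly the training rows, in training order.
    Votes are aggregated only over trees whose bootstrap excluded the
    observation; an observation in-bag for every tree gets an undefined
    similarity (logged by the caller via ``defined``).
    """
    X, _ = _as_matrix(table)
    n = X.shape[0]
    if n != model.n_train:
        raise ValueError("table rows must be exactly the training set")
    pos_votes = np.zeros(n, dtype=np.int64)
    eligible = np.zeros(n, dtype=np.int64)
    for tree, boot in zip(model.trees, model.bootstrap_indices):
        oob = np.ones(n, dtype=bool)
        oob[boot] = False
        rows = np.flatnonzero(oob)
        if rows.size == 0:
            continue
        votes = tree.votes(X[rows])
        pos_votes[rows] += votes
        eligible[rows] += 1
    return _similarity_predictions(_accessions(table, n), pos_votes,
                                   eligible, "oob",
                                   model.config.positive_weight)


def full_similarity(model: RandomForestModel, table) -> list[PUPrediction]:
    """Positive similarity using every tree in the forest (new observations)."""
    X, _ = _as_matrix(table)
    if X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} features, "
            f"got {X.shape[1]}"
        )
    n = X.shape[0]
    pos_votes = np.zeros(n, dtype=np.int64)
    for tree in model.trees:
        pos_votes += tree.votes(X)
    eligible = np.full(n, len(model.trees), dtype=np.int64)
    return _similarity_predictions(_accessions(table, n), pos_votes,
                                   eligible, "full",
                                   model.config.positive_weight)


def classify(predictions: Sequence[PUPrediction],
             cutoff: float = 0.5) -> list[str]:
    """Class calls: positive iff similarity strictly above the cutoff.

    Undefined similarities are called unlabelled.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    calls = []
    for pred in predictions:
        if pred.defined and pred.positive_similarity > cutoff:
            calls.append("positive")
        else:
            calls.append("unlabelled")
    return calls


def confusion_from_predictions(
    predictions: Sequence[PUPrediction],
    labels: Sequence[int],
    cutoff: float = 0.5,
) -> ConfusionCounts:
    """Confusion counts at a similarity cutoff; undefined predictions excluded."""
    tp = fn = tn = fp = 0
    calls = classify(predictions, cutoff)
    for pred, call, label in zip(predictions, calls, labels):
        if not pred.defined:
            continue
        positive_call = call == "positive"
        if label == 1:
            tp += positive_call
            fn += not positive_call
        else:
            fp += positive_call
            tn += not positive_call
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


def similarity_histogram(
    predictions: Sequence[PUPrediction],
    labels: Sequence[int],
    bins: int = 10,
) -> pd.DataFrame:
    """Counts of positive/unlabelled proteins per similarity bin.

    Bins are left-closed tenths of [0, 1] by default (similarity 1.0
    falls in the last bin); undefined predictions are excluded.
    """
    edges = np.linspace(0.0, 1.0, bins + 1)
    pos = np.zeros(bins, dtype=int)
    unl = np.zeros(bins, dtype=int)
    for pred, label in zip(predictions, labels):
        if not pred.defined:
            continue
        k = min(int(pred.positive_similarity * bins), bins - 1)
        if label == 1:
            pos[k] += 1
        else:
            unl[k] += 1
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:],
         "positive": pos, "unlabelled": unl}
    )


def permutation_importance(
    model: RandomForestModel,
    table,
    labels,
    seed: int = 0,
    cutoff: float = 0.5,
) -> pd.DataFrame:
    """OOB permutation importance: G-mean drop when a feature is shuffled.

    For each feature the column is permuted (seeded) and the OOB G mean
    recomputed; the importance is baseline minus permuted G mean.
    Informative features should score above pure-noise ones.
    """
    X, names = _as_matrix(table)
    y = np.asarray(labels, dtype=np.int8)
    baseline = confusion_from_predictions(
        oob_similarity(model, table), y, cutoff
    ).g_mean
    rng = np.random.default_rng(seed)
    rows = []
    for j, name in enumerate(names):
        perm = X.copy()
        perm[:, j] = rng.permutation(perm[:, j])
        gm = confusion_from_predictions(
            oob_similarity(model, perm), y, cutoff
        ).g_mean
        rows.append({"feature": name, "importance": baseline - gm})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

@dataclass
class GridSearchResult:
    grid: pd.DataFrame  # mtry, positive_weight, TP, FN, TN, FP, sens, spec, g_mean
    best_mtry: int
    best_weight: float
    best_g_mean: float
    seeds: list[int] = field(default_factory=list)


def grid_search(
    table,
    labels,
    mtry_grid: Sequence[int],
    weight_grid: Sequence[float],
    n_forests: int = 10,
    number_trees: int = 200,
    seed_list: Sequence[int] | None = None,
    min_node_size: int = 1,
    cutoff: float = 0.5,
) -> GridSearchResult:
    """Seed-shared grid search over mtry x positive weight.

    For every combination, ``n_forests`` forests are grown using exactly
    ``seed_list`` (the same seeds for every combination, so performance
    differences are attributable to the parameters alone), their OOB
    confusion counts summed, and the pooled G mean computed.  The best
    combination maximises pooled G mean; ties break toward the smaller
    weight, then the smaller mtry.
    """
    if not mtry_grid or not weight_grid:
        raise TrainingError("mtry_grid and weight_grid must be non-empty")
    if seed_list is None:
        raise TrainingError("seed_list is required (seed-shared search)")
    if len(seed_list) != n_forests:
        raise TrainingError("seed_list length must equal n_forests")
    y = np.asarray(labels, dtype=np.int8)

    rows = []
    best = None
    for weight in sorted(weight_grid):
        for mtry in sorted(mtry_grid):
            tp = fn = tn = fp = 0
            for seed in seed_list:
                config = RFConfig(
                    number_trees=number_trees, mtry=mtry,
                    positive_weight=weight, seed=int(seed),
                    min_node_size=min_node_size,
                )
                model = train_forest(table, y, config)
                preds = oob_similarity(model, table)
                cc = confusion_from_predictions(preds, y, cutoff)
                tp += cc.tp
                fn += cc.fn
                tn += cc.tn
                fp += cc.fp
            pooled = ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)
            gm = pooled.g_mean
            rows.append(
                {"mtry": mtry, "positive_weight": weight, "TP": tp,
                 "FN": fn, "TN": tn, "FP": fp,
                 "sensitivity": pooled.sensitivity,
                 "specificity": pooled.specificity, "g_mean": gm}
            )
            # Strict improvement keeps the smaller weight then mtry on ties.
            if best is None or gm > best[0]:
                best = (gm, mtry, weight)
    grid = pd.DataFrame(rows)
    return GridSearchResult(
        grid=grid, best_mtry=best[1], best_weight=best[2],
        best_g_mean=best[0], seeds=[int(s) for s in seed_list],
    )


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def predictions_to_frame(predictions: Sequence[PUPrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "accession": [p.accession for p in predictions],
            "positive_similarity": [p.positive_similarity
                                    for p in predictions],
            "eligible_trees": [p.eligible_trees for p in predictions],
            "mode": [p.mode for p in predictions],
            "predicted_class": [p.predicted_class for p in predictions],
        }
    )


def model_to_json(model: RandomForestModel) -> str:
    """Serialise a forest to a documented JSON tree format."""
    payload = {
        "config": {
            "number_trees": model.config.number_trees,
            "mtry": model.config.mtry,
            "positive_weight": model.config.positive_weight,
            "seed": model.config.seed,
            "min_node_size": model.config.min_node_size,
        },
        "n_train": model.n_train,
        "feature_names": model.feature_names,
        "trees": [
            {
                "feature": tree.feature.tolist(),
                "threshold": tree.threshold.tolist(),
                "left": tree.left.tolist(),
                "right": tree.right.tolist(),
                "weight_pos": tree.weight_pos.tolist(),
                "weight_unl": tree.weight_unl.tolist(),
            }
            for tree in model.trees
        ],
        "bootstrap_indices": [b.tolist() for b in model.bootstrap_indices],
    }
    return json.dumps(payload)


def model_from_json(text: str) -> RandomForestModel:
    payload = json.loads(text)
    trees = [
        Tree(
            feature=np.asarray(t["feature"], dtype=np.int64),
            threshold=np.asarray(t["threshold"], dtype=np.float64),
            left=np.asarray(t["left"], dtype=np.int64),
            right=np.asarray(t["right"], dtype=np.int64),
            weight_pos=np.asarray(t["weight_pos"], dtype=np.float64),
            weight_unl=np.asarray(t["weight_unl"], dtype=np.float64),
        )
        for t in payload["trees"]
    ]
    return RandomForestModel(
        trees=trees,
        bootstrap_indices=[np.asarray(b, dtype=np.int64)
                           for b in payload["bootstrap_indices"]],
        config=RFConfig(**payload["config"]),
        n_train=payload["n_train"],
        feature_names=payload["feature_names"],
    )
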