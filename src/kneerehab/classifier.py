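"""Exercise-type classification: CART decision tree plus Bayes/kNN baselines.

The primary classifier is a binary CART tree: greedy growth on Gini impurity
with an exhaustive threshold search per feature, followed by weakest-link
cost-complexity pruning with the pruning strength selected by internal
cross-validation (the subtree with minimal CV error wins; among ties the
smaller tree).  Deterministic conventions, fixed so that predictions are a
pure function of the input:

* a sample with ``feature <= threshold`` is routed to the left child;
* candidate thresholds are midpoints between consecutive distinct values;
* when two splits achieve exactly the same impurity decrease, the feature
  that comes first in the feature list wins.

Two standard baselines are provided for comparison: Gaussian naive Bayes
(per-class, per-feature normal likelihoods, product rule) and K-nearest
neighbors (Euclidean distance, majority vote, ties broken by the nearest
neighbor).  Both operate on z-score standardized features (training-set
statistics); the tree uses the raw features, as axis-aligned splits are
scale-invariant.
"""

from __future__ import annotations

import dataclasses
import logging
from copy import deepcopy

import numpy as np
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import NearestNeighbors

from .features import FEATURE_NAMES, FeatureVector

logger = logging.getLogger(__name__)

EXERCISE_TYPES = ("SAE", "SLR", "QSM")

TREE_FORMAT_HEADER = "kneerehab-tree v1"


# --------------------------------------------------------------------------
# tree structure
# --------------------------------------------------------------------------


@dataclasses.dataclass
class TreeNode:
    """Internal node (feature, threshold, children) or leaf (label)."""

    label: str
    counts: np.ndarray
    feature: int | None = None
    threshold: float = float("nan")
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves() + self.right.n_leaves()


@dataclasses.dataclass
class TreeModel:
    """A trained decision tree over named features."""

    root: TreeNode
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    ccp_alpha: float = 0.0
    cv_alphas: np.ndarray | None = None
    cv_errors: np.ndarray | None = None

    @property
    def terminal_node_count(self) -> int:
        return self.root.n_leaves()

    def predict_one(self, x: np.ndarray) -> str:
        node = self.root
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node.label

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return np.array([self.predict_one(row) for row in X])

    @property
    def root_feature(self) -> str | None:
        return None if self.root.is_leaf else self.feature_names[self.root.feature]


def _as_matrix(features) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(features, np.ndarray):
        return np.asarray(features, dtype=float), tuple(
            f"f{i}" for i in range(features.shape[1])
        )
    if len(features) and isinstance(features[0], FeatureVector):
        names = features[0].names
        return np.vstack([f.values for f in features]), tuple(names)
    X = np.asarray(features, dtype=float)
    return X, tuple(f"f{i}" for i in range(X.shape[1]))


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.sum(p * p))


def _best_split(X: np.ndarray, y: np.ndarray, n_classes: int):
    """Exhaustive (feature, threshold) search maximizing Gini decrease.

    Returns (feature, threshold, gain) or None.  Requires a *strict*
    improvement over the current best, so earlier features win exact ties.
    """
    n, p = X.shape
    counts = np.bincount(y, minlength=n_classes).astype(float)
    parent = _gini(counts)
    best = None
    best_gain = 1e-12
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), y] = 1.0
    for j in range(p):
        order = np.argsort(X[:, j], kind="mergesort")
        xs = X[order, j]
        cum = np.cumsum(onehot[order], axis=0)  # left counts for split after i
        valid = np.nonzero(xs[:-1] < xs[1:])[0]  # split between i and i+1
        if valid.size == 0:
            continue
        nl = (valid + 1).astype(float)
        nr = n - nl
        left = cum[valid]
        right = counts - left
        gini_l = 1.0 - np.sum((left / nl[:, None]) ** 2, axis=1)
        gini_r = 1.0 - np.sum((right / nr[:, None]) ** 2, axis=1)
        weighted = (nl * gini_l + nr * gini_r) / n
        gains = parent - weighted
        k = int(np.argmax(gains))
        if gains[k] > best_gain:
            best_gain = float(gains[k])
            thr = 0.5 * (xs[valid[k]] + xs[valid[k] + 1])
            best = (j, float(thr), best_gain)
    return best


def _grow(X: np.ndarray, y: np.ndarray, classes: tuple[str, ...]) -> TreeNode:
    counts = np.bincount(y, minlength=len(classes)).astype(float)
    label = classes[int(np.argmax(counts))]
    node = TreeNode(label=label, counts=counts)
    if counts.max() == counts.sum() or len(y) < 2:
        return node
    split = _best_split(X, y, len(classes))
    if split is None:
        return node
    j, thr, _ = split
    mask = X[:, j] <= thr
    node.feature = j
    node.threshold = thr
    node.left = _grow(X[mask], y[mask], classes)
    node.right = _grow(X[~mask], y[~mask], classes)
    return node


# --------------------------------------------------------------------------
# cost-complexity pruning
# --------------------------------------------------------------------------


def _subtree_errors(node: TreeNode) -> tuple[float, float, int]:
    """(node error, subtree error, leaf count), errors as misclassified counts."""
    node_err = node.counts.sum() - node.counts.max()
    if node.is_leaf:
        return node_err, node_err, 1
    _, le, ll = _subtree_errors(node.left)
    _, re_, rl = _subtree_errors(node.right)
    return node_err, le + re_, ll + rl


def _weakest_link(node: TreeNode, n_total: float):
    """Internal node with minimal g = (R(t) - R(T_t)) / (|leaves| - 1)."""
    best = None
    if node.is_leaf:
        return best
    node_err, sub_err, leaves = _subtree_errors(node)
    g = (node_err - sub_err) / n_total / max(leaves - 1, 1)
    best = (g, node)
    for child in (node.left, node.right):
        cand = _weakest_link(child, n_total)
        if cand is not None and cand[0] < best[0]:
            best = cand
    return best


def _collapse(node: TreeNode) -> None:
    node.feature = None
    node.threshold = float("nan")
    node.left = None
    node.right = None


def prune_at(root: TreeNode, alpha: float, n_total: float) -> TreeNode:
    """Weakest-link pruning: collapse nodes while their g(t) <= alpha."""
    root = deepcopy(root)
    while not root.is_leaf:
        g, node = _weakest_link(root, n_total)
        if g > alpha + 1e-15:
            break
        _collapse(node)
    return root


def pruning_path(root: TreeNode, n_total: float) -> list[float]:
    """Increasing sequence of critical alphas (starting at 0)."""
    alphas = [0.0]
    tree = deepcopy(root)
    while not tree.is_leaf:
        g, node = _weakest_link(tree, n_total)
        alphas.append(max(g, alphas[-1]))
        _collapse(node)
    return alphas


def _cv_folds(y: np.ndarray, n_folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    from sklearn.model_selection import StratifiedKFold

    _, counts = np.unique(y, return_counts=True)
    n_folds = int(min(n_folds, counts.min(), len(y)))
    if n_folds < 2:
        return []
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), y))


def train_tree(
    features,
    labels,
    max_terminal_nodes: int | None = None,
    cv_folds: int = 10,
    seed: int = 0,
) -> TreeModel:
    """Grow a CART tree and prune it to the CV-error-minimal subtree.

    Raises on single-class input.  ``max_terminal_nodes`` optionally caps the
    leaf count after CV pruning.  All CV shuffling is driven by ``seed``.
    """
    X, names = _as_matrix(features)
    labels = np.asarray(labels)
    classes = tuple(sorted(set(labels.tolist())))
    if len(classes) < 2:
        raise ValueError("train_tree requires at least 2 classes")
    y = np.array([classes.index(l) for l in labels])
    n = len(y)

    root = _grow(X, y, classes)
    alphas = np.array(pruning_path(root, n))
    # geometric midpoints between critical alphas (standard CART CV grid)
    if len(alphas) > 1:
        mids = np.sqrt(np.maximum(alphas[:-1], 1e-30) * np.maximum(alphas[1:], 1e-30))
        mids[alphas[:-1] == 0.0] = alphas[1:][alphas[:-1] == 0.0] / 2.0
        candidates = np.concatenate(([0.0], mids))
    else:
        candidates = np.array([0.0])

    folds = _cv_folds(y, cv_folds, seed)
    if folds:
        errors = np.zeros((len(folds), len(candidates)))
        for i, (tr, va) in enumerate(folds):
            fold_root = _grow(X[tr], y[tr], classes)
            for k, alpha in enumerate(candidates):
                pruned = prune_at(fold_root, alpha, len(tr))
                model = TreeModel(pruned, names, classes)
                errors[i, k] = np.mean(model.predict(X[va]) != labels[va])
        mean_err = errors.mean(axis=0)
        # minimal CV error; among ties prefer the largest alpha (smallest tree)
        best_k = int(np.max(np.nonzero(mean_err <= mean_err.min() + 1e-12)[0]))
        alpha = float(candidates[best_k])
        cv_errors = mean_err
    else:
        alpha, cv_errors = 0.0, None

    pruned = prune_at(root, alpha, n)
    model = TreeModel(
        pruned, names, classes, ccp_alpha=alpha, cv_alphas=candidates, cv_errors=cv_errors
    )
    if max_terminal_nodes is not None:
        while model.terminal_node_count > max_terminal_nodes:
            _, node = _weakest_link(model.root, n)
            _collapse(node)
    return model


def predict(model: TreeModel, feature_vector) -> str:
    """Deterministic root-to-leaf descent; ``feature <= threshold`` goes left."""
    if isinstance(feature_vector, FeatureVector):
        if tuple(feature_vector.names) != tuple(model.feature_names):
            raise ValueError("feature names do not match the trained model")
        x = feature_vector.values
    else:
        x = np.asarray(feature_vector, dtype=float)
        if x.shape != (len(model.feature_names),):
            raise ValueError(
                f"expected {len(model.feature_names)} features, got {x.shape}"
            )
    return model.predict_one(x)


# --------------------------------------------------------------------------
# serialization (human-readable nested text)
# --------------------------------------------------------------------------


def _write_node(node: TreeNode, names, lines: list[str], depth: int) -> None:
    pad = "  " * depth
    if node.is_leaf:
        lines.append(f"{pad}leaf {node.label}")
    else:
        lines.append(f"{pad}split {names[node.feature]} {node.threshold!r}")
        _write_node(node.left, names, lines, depth + 1)
        _write_node(node.right, names, lines, depth + 1)


def save_tree(model: TreeModel, path) -> None:
    lines = [TREE_FORMAT_HEADER]
    lines.append("features " + " ".join(model.feature_names))
    lines.append("classes " + " ".join(model.classes))
    _write_node(model.root, model.feature_names, lines, 0)
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")


def load_tree(path) -> TreeModel:
    from pathlib import Path

    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != TREE_FORMAT_HEADER:
        raise ValueError("not a kneerehab tree file (bad version header)")
    names = tuple(lines[1].split()[1:])
    classes = tuple(lines[2].split()[1:])
    body = lines[3:]
    pos = 0

    def parse(depth: int) -> TreeNode:
        nonlocal pos
        line = body[pos]
        pos += 1
        content = line.strip().split()
        counts = np.zeros(len(classes))
        if content[0] == "leaf":
            return TreeNode(label=content[1], counts=counts)
        node = TreeNode(label=classes[0], counts=counts)
        node.feature = names.index(content[1])
        node.threshold = float(content[2])
        node.left = parse(depth + 1)
        node.right = parse(depth + 1)
        node.label = node.left.label  # placeholder; leaves carry the decisions
        return node

    root = parse(0)
    return TreeModel(root=root, feature_names=names, classes=classes)


# --------------------------------------------------------------------------
# baselines
# --------------------------------------------------------------------------


@dataclasses.dataclass
class _Standardizer:
    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "_Standardizer":
        mean = X.mean(axis=0)
        var = X.var(axis=0)
        zero = var < 1e-9
        if zero.any():
            logger.warning(
                "zero-variance feature(s) at indices %s; variance floored at 1e-9",
                np.nonzero(zero)[0].tolist(),
            )
            var = np.where(zero, 1e-9, var)
        return cls(mean=mean, std=np.sqrt(var))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.std


@dataclasses.dataclass
class BayesModel:
    """Gaussian naive Bayes on z-scored features."""

    scaler: _Standardizer
    nb: GaussianNB
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.nb.predict(self.scaler.transform(X))


@dataclasses.dataclass
class KnnModel:
    """K-nearest-neighbor vote on z-scored features.

    Euclidean distance; majority vote among the K neighbors; when several
    classes tie for the top vote, the class of the nearest neighbor among
    the tied classes wins.
    """

    scaler: _Standardizer
    nn: NearestNeighbors
    train_labels: np.ndarray
    k: int
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        _, idx = self.nn.kneighbors(self.scaler.transform(X), n_neighbors=self.k)
        out = []
        for row in idx:
            votes: dict[str, int] = {}
            for i in row:
                lbl = self.train_labels[i]
                votes[lbl] = votes.get(lbl, 0) + 1
            top = max(votes.values())
            tied = {c for c, v in votes.items() if v == top}
            if len(tied) == 1:
                out.append(next(iter(tied)))
            else:
                # neighbors are distance-ordered: first one in a tied class wins
                out.append(next(self.train_labels[i] for i in row
                                if self.train_labels[i] in tied))
        return np.array(out)


def train_baselines(features, labels, k: int = 5) -> dict:
    """Fit the Gaussian naive Bayes and kNN baselines; returns {'bayes', 'knn'}."""
    X, names = _as_matrix(features)
    labels = np.asarray(labels)
    classes = tuple(sorted(set(labels.tolist())))
    if len(classes) < 2:
        raise ValueError("train_baselines requires at least 2 classes")
    scaler = _Standardizer.fit(X)
    Z = scaler.transform(X)
    nb = GaussianNB().fit(Z, labels)
    nn = NearestNeighbors(metric="euclidean").fit(Z)
    return {
        "bayes": BayesModel(scaler, nb, classes, names),
        "knn": KnnModel(scaler, nn, labels.copy(), min(k, len(labels)), classes, names),
    }
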