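"""CART tree, pruning, serialization, and the Bayes/kNN baselines."""

import numpy as np
import pytest

from kneerehab.classifier import (
    TreeModel,
    TreeNode,
    load_tree,
    predict,
    save_tree,
    train_baselines,
    train_tree,
)


def test_separable_1d_data_gives_depth_one_tree():
    rng = np.random.default_rng(0)
    X = np.concatenate([rng.uniform(-2, -0.5, 30), rng.uniform(0.5, 2, 30)])[:, None]
    y = ["a"] * 30 + ["b"] * 30
    model = train_tree(X, y, seed=0)
    assert model.terminal_node_count == 2
    assert -0.5 <= model.root.threshold <= 0.5  # inside the margin
    assert np.mean(model.predict(X) == np.array(y)) == 1.0


def test_xor_pattern_needs_at_least_three_leaves():
    rng = np.random.default_rng(1)
    X = rng.uniform(-1, 1, size=(200, 2))
    y = np.where(np.sign(X[:, 0]) == np.sign(X[:, 1]), "same", "diff")
    model = train_tree(X, y, seed=0)
    assert model.terminal_node_count >= 3
    assert np.mean(model.predict(X) == y) > 0.95


def test_fully_grown_tree_memorizes_training_points():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(40, 3))
    y = np.where(X[:, 0] + 0.2 * rng.normal(size=40) > 0, "p", "n")
    model = train_tree(X, y, cv_folds=1, seed=0)  # no pruning
    assert np.mean(model.predict(X) == y) == 1.0


def test_value_exactly_at_threshold_routes_left():
    left = TreeNode(label="L", counts=np.array([1.0, 0.0]))
    right = TreeNode(label="R", counts=np.array([0.0, 1.0]))
    root = TreeNode(
        label="L", counts=np.array([1.0, 1.0]), feature=0, threshold=2.5,
        left=left, right=right,
    )
    model = TreeModel(root=root, feature_names=("f0",), classes=("L", "R"))
    assert model.predict_one(np.array([2.5])) == "L"
    assert model.predict_one(np.array([2.5000001])) == "R"


def test_predict_is_deterministic_and_validates_features():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(30, 2))
    y = np.where(X[:, 1] > 0, "u", "d")
    model = train_tree(X, y, seed=0)
    x = np.array([0.3, -0.7])
    assert all(predict(model, x) == predict(model, x) for _ in range(5))
    with pytest.raises(ValueError):
        predict(model, np.array([1.0, 2.0, 3.0]))


def test_training_is_reproducible_from_seed():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(80, 4))
    y = np.where(X[:, 2] + 0.5 * rng.normal(size=80) > 0, "a", "b")
    m1 = train_tree(X, y, seed=7)
    m2 = train_tree(X, y, seed=7)
    probe = rng.normal(size=(50, 4))
    np.testing.assert_array_equal(m1.predict(probe), m2.predict(probe))


def test_single_class_input_rejected():
    with pytest.raises(ValueError, match="class"):
        train_tree(np.zeros((10, 2)), ["x"] * 10)


def test_pruning_never_increases_cv_error_estimate():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(200, 5))
    y = np.where(X[:, 0] + rng.normal(scale=0.8, size=200) > 0, "a", "b")
    model = train_tree(X, y, seed=0)
    chosen = model.cv_errors[np.argmax(model.cv_alphas == model.ccp_alpha)]
    assert chosen <= model.cv_errors[0] + 1e-12  # <= unpruned tree's CV error
    full = train_tree(X, y, cv_folds=1, seed=0)
    assert model.terminal_node_count <= full.terminal_node_count


def test_max_terminal_nodes_cap():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(150, 4))
    y = np.where(X[:, 0] * X[:, 1] > 0, "a", "b")
    model = train_tree(X, y, cv_folds=1, max_terminal_nodes=4, seed=0)
    assert model.terminal_node_count <= 4


def test_tree_serialization_round_trip(tmp_path):
    rng = np.random.default_rng(7)
    X = rng.normal(size=(100, 3))
    y = np.where(X[:, 0] - X[:, 2] > 0.2, "pos", "neg")
    model = train_tree(X, y, seed=0)
    path = tmp_path / "model.txt"
    save_tree(model, path)
    text = path.read_text()
    assert text.startswith("kneerehab-tree v1")
    back = load_tree(path)
    probe = rng.normal(size=(60, 3))
    np.testing.assert_array_equal(model.predict(probe), back.predict(probe))


def test_load_tree_rejects_bad_header(tmp_path):
    path = tmp_path / "junk.txt"
    path.write_text("not a model\n")
    with pytest.raises(ValueError, match="header"):
        load_tree(path)


# --------------------------------------------------------------------------
# baselines
# --------------------------------------------------------------------------


def knn_brute_oracle(X_train, y_train, x, k):
    """All-pairs Euclidean scan with majority vote, nearest-neighbor tie-break."""
    d = np.linalg.norm(X_train - x, axis=1)
    order = np.argsort(d, kind="stable")[:k]
    labels = y_train[order]
    votes = {}
    for lbl in labels:
        votes[lbl] = votes.get(lbl, 0) + 1
    top = max(votes.values())
    tied = {c for c, v in votes.items() if v == top}
    return next(l for l in labels if l in tied)


def test_knn_matches_brute_force_scan():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(120, 4))
    y = np.array(["a", "b", "c"] * 40)
    knn = train_baselines(X, y, k=5)["knn"]
    Z = knn.scaler.transform(X)
    probes = rng.normal(size=(40, 4))
    Zp = knn.scaler.transform(probes)
    expected = [knn_brute_oracle(Z, y, zp, 5) for zp in Zp]
    np.testing.assert_array_equal(knn.predict(probes), expected)


def test_knn_k1_memorizes_training_data():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(60, 3))
    y = np.array(["a", "b"] * 30)
    knn = train_baselines(X, y, k=1)["knn"]
    np.testing.assert_array_equal(knn.predict(X), y)


def test_bayes_on_well_separated_gaussians():
    rng = np.random.default_rng(10)
    X = np.concatenate([rng.normal(-2, 0.5, (500, 1)), rng.normal(2, 0.5, (500, 1))])
    y = np.array(["lo"] * 500 + ["hi"] * 500)
    bayes = train_baselines(X, y)["bayes"]
    assert np.mean(bayes.predict(X) == y) > 0.99
    # decision boundary near the midpoint of the two class means
    assert bayes.predict(np.array([[-0.2]]))[0] == "lo"
    assert bayes.predict(np.array([[0.2]]))[0] == "hi"


def test_zero_variance_feature_floored_with_warning(caplog):
    rng = np.random.default_rng(11)
    X = np.column_stack([rng.normal(size=40), np.full(40, 3.0)])  # constant column
    y = np.array(["a", "b"] * 20)
    with caplog.at_level("WARNING", logger="kneerehab.classifier"):
        models = train_baselines(X, y)
    assert any("zero-variance" in r.message for r in caplog.records)
    assert np.isfinite(models["bayes"].scaler.std).all()


def test_tree_accuracy_tracks_sklearn_reference():
    """Independent cross-check: the in-house CART matches sklearn's tree
    accuracy on the same held-out split to within a few points."""
    from sklearn.model_selection import train_test_split
    from sklearn.tree import DecisionTreeClassifier

    rng = np.random.default_rng(12)
    n = 400
    X = rng.normal(size=(n, 6))
    y = np.where(
        X[:, 0] + 0.8 * X[:, 1] - X[:, 2] + rng.normal(scale=0.7, size=n) > 0, "a", "b"
    )
    Xtr, Xte, ytr, yte = train_test_split(X, y, test_size=0.4, random_state=0)
    mine = train_tree(Xtr, ytr, seed=0)
    acc_mine = np.mean(mine.predict(Xte) == yte)
    ref = DecisionTreeClassifier(ccp_alpha=0.01, random_state=0).fit(Xtr, ytr)
    acc_ref = ref.score(Xte, yte)
    assert abs(acc_mine - acc_ref) < 0.06
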