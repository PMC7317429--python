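"""Regression-tree growth, pruning, and the one-SE rule."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_best_split
from leafsi.tree import best_split, grow_tree, prune_one_se


def _step_data(threshold=0.43, n=60, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.sort(rng.uniform(0.0, 1.0, n))
    y = np.where(x < threshold, 1.0, 5.0) + rng.normal(0.0, noise, n)
    return pd.DataFrame({"soil_n": x}), y


def test_noiseless_step_split_at_straddling_midpoint():
    X, y = _step_data()
    tree = grow_tree(X, y, min_leaf=5)
    var, thr = tree.first_split
    assert var == "soil_n"
    xs = X["soil_n"].to_numpy()
    lo = xs[xs < 0.43].max()
    hi = xs[xs >= 0.43].min()
    assert thr == pytest.approx(0.5 * (lo + hi), abs=1e-12)
    means = sorted(leaf.mean for leaf in tree.root.leaves())
    assert means == [1.0, 5.0]


@pytest.mark.parametrize("seed", range(6))
def test_first_split_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 80
    X = pd.DataFrame({
        "a": rng.uniform(size=n),
        "b": rng.integers(0, 2, n).astype(float),
        "c": rng.normal(size=n),
    })
    y = (2.0 * (X["a"] > 0.5) + X["b"] + rng.normal(0, 0.5, n)).to_numpy()
    found = best_split(X.to_numpy(), y, min_leaf=7)
    oracle = brute_force_best_split(X.to_numpy(), y, min_leaf=7)
    assert found is not None and oracle is not None
    j, thr, red = found
    oj, othr, ored = oracle
    assert (j, thr) == (oj, pytest.approx(othr, abs=1e-12))
    assert red == pytest.approx(ored, rel=1e-9)


def test_constant_response_single_node():
    X = pd.DataFrame({"x": np.linspace(0, 1, 40)})
    tree = grow_tree(X, np.full(40, 3.7), min_leaf=5)
    assert tree.n_leaves == 1
    assert tree.root.mean == 3.7


def test_constant_predictor_never_split_on():
    rng = np.random.default_rng(1)
    X = pd.DataFrame({"flat": np.ones(60), "x": rng.uniform(size=60)})
    y = (X["x"] > 0.5).to_numpy().astype(float)
    tree = grow_tree(X, y, min_leaf=5)
    used = set()

    def walk(node):
        if not node.is_leaf:
            used.add(node.var)
            walk(node.left)
            walk(node.right)

    walk(tree.root)
    assert "flat" not in used


def test_noiseless_threshold_pruned_to_single_split():
    X, y = _step_data(n=100)
    tree = grow_tree(X, y, min_leaf=5)
    pruned = prune_one_se(tree, k_folds=10, seed=0)
    assert pruned.n_leaves == 2
    assert pruned.first_split[0] == "soil_n"


def test_pure_noise_pruned_to_root():
    """Without signal the one-SE rule collapses the tree almost always."""
    roots = 0
    reps = 100
    for rep in range(reps):
        rng = np.random.default_rng(rep)
        X = pd.DataFrame({"a": rng.uniform(size=120), "b": rng.normal(size=120)})
        y = rng.normal(size=120)
        tree = grow_tree(X, y, min_leaf=7)
        pruned = prune_one_se(tree, k_folds=10, seed=rep)
        roots += pruned.n_leaves == 1
    assert roots / reps >= 0.9


def test_resubstitution_error_nonincreasing_in_size():
    X, y = _step_data(n=200, noise=1.0, seed=3)
    tree = grow_tree(X, y, min_leaf=7, cp_min=0.001)
    pruned = prune_one_se(tree, k_folds=5, seed=1)
    tab = pruned.cp_table.sort_values("n_leaves")
    assert (np.diff(tab["rel_error"].to_numpy()) <= 1e-12).all()


def _is_subtree(sub, full):
    if sub.is_leaf:
        return True
    if full.is_leaf or sub.var != full.var or sub.threshold != full.threshold:
        return False
    return _is_subtree(sub.left, full.left) and _is_subtree(sub.right, full.right)


def test_pruned_tree_is_subtree_and_predicts_leaf_means():
    rng = np.random.default_rng(9)
    n = 300
    X = pd.DataFrame({"a": rng.uniform(size=n), "b": rng.normal(size=n)})
    y = 2.0 * (X["a"] > 0.4) + 1.0 * (X["b"] > 0) + rng.normal(0, 0.7, n)
    tree = grow_tree(X, y.to_numpy(), min_leaf=7, cp_min=0.005)
    pruned = prune_one_se(tree, k_folds=10, seed=2)
    assert _is_subtree(pruned.root, tree.root)
    # piecewise-constant predictions reproduce leaf means exactly
    pred = pruned.predict(X)
    df = pd.DataFrame({"pred": pred, "y": y})
    grp = df.groupby("pred")["y"].mean()
    assert np.allclose(grp.index.to_numpy(), grp.to_numpy(), atol=1e-10)
    # selected complexity obeys the one-SE inequality
    tab = pruned.cp_table
    i_min = tab["xerror"].idxmin()
    sel_rows = tab[tab["cp"] <= pruned.selected_cp + 1e-15]
    assert (tab["xerror"] >= 0).all()
    chosen = tab[np.isclose(tab["cp"], pruned.selected_cp)]
    assert (chosen["xerror"] <= tab.loc[i_min, "xerror"]
            + tab.loc[i_min, "xstd"] + 1e-12).all()
    assert sel_rows is not None


def test_kfold_bounds_validated():
    X, y = _step_data(n=30)
    tree = grow_tree(X, y, min_leaf=5)
    with pytest.raises(ValueError, match="k_folds"):
        prune_one_se(tree, k_folds=1, seed=0)
    with pytest.raises(ValueError, match="k_folds"):
        prune_one_se(tree, k_folds=31, seed=0)


def test_serialization_roundtrip_text_and_json():
    import json

    X, y = _step_data(n=80, noise=0.3, seed=5)
    pruned = prune_one_se(grow_tree(X, y, min_leaf=7), k_folds=5, seed=0)
    txt = pruned.to_text()
    assert "soil_n" in txt or "leaf" in txt
    payload = json.loads(pruned.to_json())
    assert "tree" in payload and "cp_table" in payload
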