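"""CART regression trees with cost-complexity pruning and the one-SE rule.

Used to detect threshold structure in leaf Si — e.g. a soil-nitrogen
threshold below which the fertilization response appears.  Trees are grown
by greedy binary splitting on pooled within-node sum of squared errors
(SSE); split thresholds sit at the midpoint between adjacent sorted
predictor values; a split is kept only if it reduces the overall relative
error by at least ``cp_min`` (complexity parameter scaled by the root SSE)
and both children hold at least ``min_leaf`` observations.

Pruning follows the weakest-link cost-complexity sequence.  K-fold
cross-validation (folds stratified by site when labels are given) scores
each complexity value, and the one-standard-error rule selects the largest
complexity (smallest tree) whose CV error is within one SE of the minimum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TreeNode", "RegressionTree", "grow_tree", "prune_one_se", "best_split"]


@dataclass
class TreeNode:
    mean: float
    n: int
    sse: float
    var: str | None = None          # split variable; None for a leaf
    threshold: float | None = None  # go left when x < threshold
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.var is None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def subtree_sse(self) -> float:
        return sum(l.sse for l in self.leaves())

    def copy(self) -> "TreeNode":
        return TreeNode(self.mean, self.n, self.sse, self.var, self.threshold,
                        self.left.copy() if self.left else None,
                        self.right.copy() if self.right else None)


@dataclass
class RegressionTree:
    root: TreeNode
    columns: list[str]
    root_sse: float
    min_leaf: int
    cp_min: float
    cp_table: pd.DataFrame | None = None
    selected_cp: float | None = None
    _X: np.ndarray = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)
    _strata: np.ndarray = field(repr=False, default=None)

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    @property
    def first_split(self) -> tuple[str, float] | None:
        if self.root.is_leaf:
            return None
        return self.root.var, self.root.threshold

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        M = X[self.columns].to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        col = {c: i for i, c in enumerate(self.columns)}
        out = np.empty(len(M))
        for i, row in enumerate(M):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[col[node.var]] < node.threshold else node.right
            out[i] = node.mean
        return out

    def to_text(self) -> str:
        lines: list[str] = []

        def rec(node: TreeNode, indent: str, tag: str) -> None:
            if node.is_leaf:
                lines.append(f"{indent}{tag}leaf: mean={node.mean:.4g} n={node.n}")
            else:
                lines.append(f"{indent}{tag}{node.var} < {node.threshold:.4g} "
                             f"(n={node.n}, mean={node.mean:.4g})")
                rec(node.left, indent + "  ", "yes: ")
                rec(node.right, indent + "  ", "no:  ")

        rec(self.root, "", "")
        return "\n".join(lines)

    def to_json(self) -> str:
        def rec(node: TreeNode) -> dict:
            d = {"mean": node.mean, "n": node.n, "sse": node.sse}
            if not node.is_leaf:
                d.update(var=node.var, threshold=node.threshold,
                         left=rec(node.left), right=rec(node.right))
            return d

        payload = {"tree": rec(self.root), "selected_cp": self.selected_cp}
        if self.cp_table is not None:
            payload["cp_table"] = self.cp_table.to_dict(orient="records")
        return json.dumps(payload, indent=2)


def _node_sse(y: np.ndarray) -> float:
    return float(((y - y.mean()) ** 2).sum())


def best_split(X: np.ndarray, y: np.ndarray, min_leaf: int
               ) -> tuple[int, float, float] | None:
    """Best (variable index, threshold, SSE reduction) over all binary cuts.

    Scans every candidate cut of every column via cumulative sums.  Ties are
    broken toward the lowest column index, then the smallest threshold.
    Returns None when no admissible cut reduces SSE.
    """
    n = len(y)
    parent_sse = _node_sse(y)
    best: tuple[int, float, float] | None = None
    for j in range(X.shape[1]):
        x = X[:, j]
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        cs = np.cumsum(ys)
        cs2 = np.cumsum(ys**2)
        total, total2 = cs[-1], cs2[-1]
        i = np.arange(1, n)  # left size
        sse_l = cs2[:-1] - cs[:-1] ** 2 / i
        sse_r = (total2 - cs2[:-1]) - (total - cs[:-1]) ** 2 / (n - i)
        red = parent_sse - (sse_l + sse_r)
        valid = (i >= min_leaf) & (i <= n - min_leaf) & (xs[1:] > xs[:-1])
        if not valid.any():
            continue
        red = np.where(valid, red, -np.inf)
        k = int(np.argmax(red))  # argmax takes the first (smallest threshold) tie
        if red[k] <= 1e-12 * max(parent_sse, 1.0):
            continue
        thr = 0.5 * (xs[k] + xs[k + 1])
        if best is None or red[k] > best[2] + 1e-12 * max(parent_sse, 1.0):
            best = (j, float(thr), float(red[k]))
    return best


def _grow(X: np.ndarray, y: np.ndarray, min_leaf: int, cp_abs: float,
          columns: list[str]) -> TreeNode:
    node = TreeNode(mean=float(y.mean()), n=len(y), sse=_node_sse(y))
    if len(y) < 2 * min_leaf or node.sse <= 0:
        return node
    found = best_split(X, y, min_leaf)
    if found is None or found[2] < cp_abs:
        return node
    j, thr, _ = found
    mask = X[:, j] < thr
    node.var = columns[j]
    node.threshold = thr
    node.left = _grow(X[mask], y[mask], min_leaf, cp_abs, columns)
    node.right = _grow(X[~mask], y[~mask], min_leaf, cp_abs, columns)
    return node


def grow_tree(X: pd.DataFrame, y: np.ndarray | pd.Series, min_leaf: int = 7,
              cp_min: float = 0.01, strata: np.ndarray | None = None) -> RegressionTree:
    """Grow the full tree.  ``strata`` (e.g. site labels) steers CV folds later."""
    if isinstance(y, pd.Series):
        y = y.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    columns = list(X.columns)
    M = X.to_numpy(dtype=float)
    if len(y) != len(M):
        raise ValueError("X and y lengths differ")
    if len(y) < 2 * min_leaf:
        raise ValueError(f"need at least {2 * min_leaf} observations to attempt a split")
    root_sse = _node_sse(y)
    cp_abs = cp_min * root_sse if root_sse > 0 else np.inf
    root = _grow(M, y, min_leaf, cp_abs, columns)
    return RegressionTree(root=root, columns=columns, root_sse=root_sse,
                          min_leaf=min_leaf, cp_min=cp_min,
                          _X=M, _y=y,
                          _strata=np.asarray(strata) if strata is not None else None)


# ---------------------------------------------------------------------------
# cost-complexity pruning

def _weakest_link_sequence(root: TreeNode) -> list[tuple[float, TreeNode]]:
    """Nested pruning sequence [(alpha_k, tree_k)] from alpha=0 to the stump."""
    seq: list[tuple[float, TreeNode]] = [(0.0, root.copy())]
    current = root.copy()
    while not current.is_leaf:
        # g(t) = (sse(t) - sse(leaves under t)) / (|leaves| - 1)
        def links(node: TreeNode, acc: list) -> None:
            if node.is_leaf:
                return
            nl = len(node.leaves())
            acc.append(((node.sse - node.subtree_sse()) / (nl - 1), node))
            links(node.left, acc)
            links(node.right, acc)

        acc: list[tuple[float, TreeNode]] = []
        links(current, acc)
        g_min = min(g for g, _ in acc)
        for g, node in acc:
            if g <= g_min + 1e-12 * (1.0 + abs(g_min)):
                node.var = node.threshold = node.left = node.right = None
        seq.append((g_min, current.copy()))
    return seq


def _prune_at(root: TreeNode, alpha: float) -> TreeNode:
    """Smallest minimizing subtree of the cost-complexity criterion at alpha."""
    tree = root.copy()
    changed = True
    while changed:
        changed = False

        def rec(node: TreeNode) -> None:
            nonlocal changed
            if node.is_leaf:
                return
            rec(node.left)
            rec(node.right)
            nl = len(node.leaves())
            g = (node.sse - node.subtree_sse()) / (nl - 1)
            if g <= alpha * (1 + 1e-12):
                node.var = node.threshold = node.left = node.right = None
                changed = True

        rec(tree)
    return tree


def _stratified_folds(n: int, k: int, rng: np.random.Generator,
                      strata: np.ndarray | None) -> np.ndarray:
    """Fold labels 0..k-1, balanced within each stratum."""
    fold = np.empty(n, dtype=int)
    if strata is None:
        strata = np.zeros(n, dtype=int)
    offset = 0
    for s in pd.unique(strata):
        idx = np.flatnonzero(strata == s)
        idx = rng.permutation(idx)
        fold[idx] = (np.arange(len(idx)) + offset) % k
        offset += len(idx)  # rotate so small strata don't all start at fold 0
    return fold


def prune_one_se(tree: RegressionTree, k_folds: int = 10, seed: int = 0) -> RegressionTree:
    """Cross-validate the pruning sequence and apply the one-SE rule.

    CV error per complexity value is the summed holdout SSE relative to the
    full-data root SSE; its SE is estimated from the spread of fold errors.
    The selected complexity is the largest one whose CV error does not
    exceed the minimum by more than one SE; the returned tree is the full
    tree pruned at that complexity.
    """
    n = len(tree._y)
    if k_folds < 2 or k_folds > n:
        raise ValueError(f"k_folds must lie in [2, {n}]")
    seq = _weakest_link_sequence(tree.root)
    alphas = np.array([a for a, _ in seq])
    sizes = np.array([len(t.leaves()) for _, t in seq])
    rel_error = np.array([t.subtree_sse() for _, t in seq]) / max(tree.root_sse, 1e-300)
    # evaluate between consecutive alphas (geometric means, rpart-style)
    upper = np.append(alphas[1:], alphas[-1] * 10 + 1.0)
    betas = np.sqrt(np.maximum(alphas, 1e-30) * np.maximum(upper, 1e-30))
    betas[0] = 0.0 if alphas[0] == 0 else betas[0]

    rng = np.random.default_rng(seed)
    fold = _stratified_folds(n, k_folds, rng, tree._strata)
    cv_sse = np.zeros((k_folds, len(betas)))
    for f in range(k_folds):
        tr, ho = fold != f, fold == f
        sub = grow_tree(pd.DataFrame(tree._X[tr], columns=tree.columns),
                        tree._y[tr], min_leaf=tree.min_leaf, cp_min=tree.cp_min)
        scale = sub.root_sse / max(tree.root_sse, 1e-300)  # alpha is per-dataset
        Xho = tree._X[ho]
        yho = tree._y[ho]
        for b, beta in enumerate(betas):
            pruned_root = _prune_at(sub.root, beta * scale)
            pruned = RegressionTree(root=pruned_root, columns=tree.columns,
                                    root_sse=sub.root_sse, min_leaf=tree.min_leaf,
                                    cp_min=tree.cp_min)
            pred = pruned.predict(Xho)
            cv_sse[f, b] = float(((yho - pred) ** 2).sum())

    denom = max(tree.root_sse, 1e-300)
    xerror = cv_sse.sum(axis=0) / denom
    # fold totals scaled to the full-data level act as k replicate estimates
    xstd = (cv_sse * k_folds / denom).std(axis=0, ddof=1) / math.sqrt(k_folds)

    i_min = int(np.argmin(xerror))
    cutoff = xerror[i_min] + xstd[i_min]
    admissible = np.flatnonzero(xerror <= cutoff)
    i_sel = int(admissible.max())  # largest complexity = smallest tree
    selected_alpha = alphas[i_sel]

    pruned_root = _prune_at(tree.root, selected_alpha)
    cp_table = pd.DataFrame({
        "cp": alphas / denom,
        "n_leaves": sizes,
        "rel_error": rel_error,
        "xerror": xerror,
        "xstd": xstd,
    })
    return RegressionTree(root=pruned_root, columns=tree.columns,
                          root_sse=tree.root_sse, min_leaf=tree.min_leaf,
                          cp_min=tree.cp_min, cp_table=cp_table,
                          selected_cp=float(selected_alpha / denom),
                          _X=tree._X, _y=tree._y, _strata=tree._strata)
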