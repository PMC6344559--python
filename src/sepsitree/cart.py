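"""Classification-tree derivation for binary clinical outcomes (CART).

Recursive binary partitioning over the seven candidate predictors (five
serum biomarkers, age, platelet count) using weighted Gini impurity:

* every candidate split is a midpoint between consecutive distinct
  observed values of one predictor; left child receives values <= the
  threshold, right child values > it;
* class weighting (``balanced``) rescales event/non-event contributions by
  inverse prevalence at the root, so rare outcomes (5-15% prevalence) can
  dominate splits and yield the high-sensitivity trees this analysis is
  after;
* growth stops at ``max_depth``, ``min_node_size``, node purity, or when
  no admissible split improves weighted impurity;
* pruning generates the cost-complexity sequence of nested subtrees
  (weakest-link collapsing) and selects the subtree maximizing pooled
  cross-validated AUC, preferring the smaller subtree on ties;
* the summary cross-validated AUC pools all out-of-fold risk predictions
  (each held-out episode receives its terminal node's training event rate)
  and computes one AUC, rather than averaging per-fold AUCs.

Everything is deterministic given the data, the configuration, and the CV
seed: row order is normalized internally and equal-gain splits break ties
by variable name then by smaller threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import PREDICTORS
from .evaluation import hanley_mcneil_se, roc_auc_with_ci
from .risk_tree import SplitRule, TreeNode, TreeSpec, label_risk, validate_tree

_GAIN_EPS = 1e-12


class CartError(ValueError):
    pass


@dataclass(frozen=True)
class CartConfig:
    """Knobs of the tree-growing procedure.

    Defaults (``min_node_size=20``, ``max_depth=4``, balanced class
    weights, 10-fold CV pruning) are sized for ~400-episode cohorts and
    produce trees of roughly five terminal nodes.
    """

    min_node_size: int = 20
    max_depth: int = 4
    class_weighting: str = "balanced"  # "none" | "balanced"
    min_impurity_decrease: float = 0.0
    cv_folds: int = 10
    cv_seed: int = 0
    prune: bool = True

    def __post_init__(self) -> None:
        if self.min_node_size < 1:
            raise CartError("min_node_size must be >= 1")
        if self.max_depth < 1:
            raise CartError("max_depth must be >= 1")
        if self.cv_folds < 2:
            raise CartError("cv_folds must be >= 2")
        if self.class_weighting not in ("none", "balanced"):
            raise CartError(f"unknown class_weighting {self.class_weighting!r}")
        if self.min_impurity_decrease < 0:
            raise CartError("min_impurity_decrease must be >= 0")


def gini_impurity(
    n_event: float, n_nonevent: float, w_event: float = 1.0, w_nonevent: float = 1.0
) -> float:
    """Weighted Gini impurity 1 - sum(p_c^2) over weight-adjusted class
    proportions; 0 for a pure node, 0.5 for a (weighted-)balanced one."""
    if n_event + n_nonevent <= 0:
        raise CartError("empty node has no impurity")
    if min(w_event, w_nonevent) <= 0:
        raise CartError("class weights must be > 0")
    m1 = w_event * n_event
    m0 = w_nonevent * n_nonevent
    p1 = m1 / (m1 + m0)
    return 1.0 - p1 * p1 - (1.0 - p1) * (1.0 - p1)


def class_weights(y: np.ndarray, scheme: str) -> tuple[float, float]:
    """(w_event, w_nonevent); ``balanced`` uses inverse-prevalence weights
    n / (2 * n_c) computed at the root."""
    n = len(y)
    n1 = int(y.sum())
    n0 = n - n1
    if scheme == "none" or n1 == 0 or n0 == 0:
        return 1.0, 1.0
    return n / (2.0 * n1), n / (2.0 * n0)


@dataclass
class BestSplit:
    variable: str
    threshold: float
    gain: float  # weighted impurity decrease


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    variables: Sequence[str],
    config: CartConfig,
    weights: Optional[tuple[float, float]] = None,
) -> Optional[BestSplit]:
    """Exhaustive search for the best admissible binary split of one node.

    Evaluates the midpoint between every pair of consecutive distinct
    sorted values of every candidate variable and returns the rule with the
    largest weighted impurity decrease, subject to both children holding at
    least ``min_node_size`` episodes.  Returns ``None`` when the node is
    pure or no admissible split improves impurity by more than
    ``min_impurity_decrease``.  Ties break to the alphabetically first
    variable, then the smallest threshold.
    """
    n = len(y)
    if n == 0:
        raise CartError("empty node")
    n1 = int(y.sum())
    if n1 == 0 or n1 == n:
        return None
    w1, w0 = weights if weights is not None else class_weights(y, config.class_weighting)

    parent_imp = gini_impurity(n1, n - n1, w1, w0)
    w_parent = w1 * n1 + w0 * (n - n1)
    best: Optional[BestSplit] = None
    min_gain = max(config.min_impurity_decrease, _GAIN_EPS)

    order_vars = sorted(range(len(variables)), key=lambda j: variables[j])
    for j in order_vars:
        x = X[:, j]
        order = np.argsort(x, kind="mergesort")
        xs = x[order]
        ys = y[order]
        cum_e = np.cumsum(ys)
        # split after position i (1-based count on the left)
        i = np.arange(1, n)
        valid = xs[1:] != xs[:-1]
        valid &= (i >= config.min_node_size) & (n - i >= config.min_node_size)
        if not valid.any():
            continue
        nl = i[valid].astype(float)
        el = cum_e[:-1][valid].astype(float)
        nr = n - nl
        er = n1 - el
        ml = w1 * el + w0 * (nl - el)
        mr = w1 * er + w0 * (nr - er)
        # weighted Gini of each child: 2 * m1 * m0 / m^2
        imp_l = 2 * (w1 * el) * (w0 * (nl - el)) / ml**2
        imp_r = 2 * (w1 * er) * (w0 * (nr - er)) / mr**2
        gain = parent_imp - (ml * imp_l + mr * imp_r) / w_parent
        k = int(np.argmax(gain))
        g = float(gain[k])
        if g <= min_gain:
            continue
        pos = i[valid][k]
        thr = float((xs[pos - 1] + xs[pos]) / 2.0)
        if best is None or g > best.gain + _GAIN_EPS:
            best = BestSplit(variables[j], thr, g)
    return best


# ---------------------------------------------------------------------------
# Internal mutable tree used during growth and pruning


class _Node:
    __slots__ = ("idx", "n", "n_event", "depth", "variable", "threshold",
                 "left", "right", "gain")

    def __init__(self, idx: np.ndarray, y: np.ndarray, depth: int):
        self.idx = idx
        self.n = int(len(idx))
        self.n_event = int(y[idx].sum())
        self.depth = depth
        self.variable: Optional[str] = None
        self.threshold: float = math.nan
        self.left: Optional[_Node] = None
        self.right: Optional[_Node] = None
        self.gain: float = 0.0

    @property
    def is_terminal(self) -> bool:
        return self.left is None

    def rate(self) -> float:
        return self.n_event / self.n

    def leaves(self) -> list["_Node"]:
        if self.is_terminal:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def internal(self) -> list["_Node"]:
        if self.is_terminal:
            return []
        return [self] + self.left.internal() + self.right.internal()

    def collapse(self) -> None:
        self.variable = None
        self.threshold = math.nan
        self.left = None
        self.right = None

    def predict_one(self, row: np.ndarray, var_index: dict[str, int]) -> float:
        node = self
        while not node.is_terminal:
            v = row[var_index[node.variable]]
            node = node.left if v <= node.threshold else node.right
        return node.rate()


def _check_matrix(X: np.ndarray, y: np.ndarray, variables: Sequence[str]) -> None:
    if X.ndim != 2 or X.shape[1] != len(variables):
        raise CartError("X must be (n, n_variables)")
    if len(y) != X.shape[0]:
        raise CartError("X and y length mismatch")
    if np.isnan(X).any():
        raise CartError("predictor matrix contains missing values")


def _grow(
    X: np.ndarray, y: np.ndarray, variables: Sequence[str], config: CartConfig,
    weights: tuple[float, float],
) -> _Node:
    root = _Node(np.arange(len(y)), y, 0)
    stack = [root]
    while stack:
        node = stack.pop()
        if node.depth >= config.max_depth or node.n < 2 * config.min_node_size:
            continue
        found = best_split(X[node.idx], y[node.idx], variables, config, weights)
        if found is None:
            continue
        j = list(variables).index(found.variable)
        mask = X[node.idx, j] <= found.threshold
        node.variable = found.variable
        node.threshold = found.threshold
        node.gain = found.gain
        node.left = _Node(node.idx[mask], y, node.depth + 1)
        node.right = _Node(node.idx[~mask], y, node.depth + 1)
        stack.extend([node.right, node.left])
    return root


def _to_spec(root: _Node, outcome_name: str) -> TreeSpec:
    """Freeze an internal tree into a validated TreeSpec (BFS node ids)."""
    nodes: dict[str, TreeNode] = {}
    queue: list[tuple[_Node, str]] = [(root, "1")]
    counter = 1
    while queue:
        node, nid = queue.pop(0)
        if node.is_terminal:
            nodes[nid] = TreeNode(nid, n=node.n, n_event=node.n_event)
        else:
            lid, rid = str(counter + 1), str(counter + 2)
            counter += 2
            nodes[nid] = TreeNode(
                nid, n=node.n, n_event=node.n_event,
                split=SplitRule(node.variable, node.threshold),
                children=(lid, rid),
            )
            queue.append((node.left, lid))
            queue.append((node.right, rid))
    spec = TreeSpec(
        outcome_name=outcome_name,
        baseline_rate=root.rate(),
        nodes=nodes,
        root_id="1",
    )
    label_risk(spec)
    validate_tree(spec)
    return spec


def grow_tree(
    X: np.ndarray,
    y: Sequence[bool],
    variables: Sequence[str],
    config: CartConfig = CartConfig(),
    outcome_name: str = "outcome",
) -> TreeSpec:
    """Grow an (unpruned) classification tree and return its TreeSpec.

    Row order does not affect the result.  A constant outcome yields a
    single-node tree.
    """
    y = np.asarray(y, dtype=bool)
    X = np.asarray(X, dtype=float)
    _check_matrix(X, y, variables)
    weights = class_weights(y, config.class_weighting)
    root = _grow(X, y, variables, config, weights)
    return _to_spec(root, outcome_name)


# ---------------------------------------------------------------------------
# Cost-complexity pruning


def _subtree_risk(node: _Node, w: tuple[float, float], w_root: float) -> float:
    """Total weighted impurity of the leaves under ``node``, as a fraction
    of the root's weighted mass."""
    total = 0.0
    for leaf in node.leaves():
        e, ne = leaf.n_event, leaf.n - leaf.n_event
        mass = w[0] * e + w[1] * ne
        total += mass / w_root * gini_impurity(e, ne, w[0], w[1])
    return total


def _node_risk(node: _Node, w: tuple[float, float], w_root: float) -> float:
    e, ne = node.n_event, node.n - node.n_event
    mass = w[0] * e + w[1] * ne
    return mass / w_root * gini_impurity(e, ne, w[0], w[1])


def _weakest_link_alphas(root: _Node, w: tuple[float, float]) -> list[float]:
    """Critical complexity values at which successive subtrees collapse."""
    w_root = w[0] * root.n_event + w[1] * (root.n - root.n_event)
    alphas: list[float] = [0.0]
    # operate on a deep copy so the caller's tree is untouched
    work = _copy_tree(root)
    while not work.is_terminal:
        best_g = math.inf
        for t in work.internal():
            g = (_node_risk(t, w, w_root) - _subtree_risk(t, w, w_root)) / (
                len(t.leaves()) - 1
            )
            best_g = min(best_g, g)
        alphas.append(best_g)
        for t in work.internal():
            g = (_node_risk(t, w, w_root) - _subtree_risk(t, w, w_root)) / (
                len(t.leaves()) - 1
            )
            if g <= best_g + _GAIN_EPS and not t.is_terminal:
                t.collapse()
    return sorted(set(alphas))


def _copy_tree(node: _Node) -> _Node:
    clone = _Node.__new__(_Node)
    clone.idx = node.idx
    clone.n = node.n
    clone.n_event = node.n_event
    clone.depth = node.depth
    clone.variable = node.variable
    clone.threshold = node.threshold
    clone.gain = node.gain
    clone.left = _copy_tree(node.left) if node.left is not None else None
    clone.right = _copy_tree(node.right) if node.right is not None else None
    return clone


def _prune_at(root: _Node, alpha: float, w: tuple[float, float]) -> _Node:
    """Smallest subtree optimal at complexity ``alpha`` (weakest-link)."""
    work = _copy_tree(root)
    w_root = w[0] * work.n_event + w[1] * (work.n - work.n_event)
    changed = True
    while changed and not work.is_terminal:
        changed = False
        for t in work.internal():
            g = (_node_risk(t, w, w_root) - _subtree_risk(t, w, w_root)) / (
                len(t.leaves()) - 1
            )
            if g <= alpha + _GAIN_EPS:
                t.collapse()
                changed = True
                break
    return work


def _stratified_folds(
    y: np.ndarray, k: int, seed: int
) -> np.ndarray:
    """Fold labels 0..k-1, stratified by class; every fold gets events
    whenever the event count allows it."""
    n1 = int(y.sum())
    if n1 < k:
        raise CartError(
            f"cannot stratify {n1} events into {k} folds; every fold needs one"
        )
    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    for cls in (True, False):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def _cv_risks_for_alphas(
    X: np.ndarray, y: np.ndarray, variables: Sequence[str], config: CartConfig,
    alphas: list[float],
) -> np.ndarray:
    """Pooled out-of-fold risk matrix, one column per candidate alpha."""
    folds = _stratified_folds(y, config.cv_folds, config.cv_seed)
    var_index = {v: j for j, v in enumerate(variables)}
    risks = np.empty((len(y), len(alphas)))
    for f in range(config.cv_folds):
        train = folds != f
        test = ~train
        w = class_weights(y[train], config.class_weighting)
        subroot = _grow(X[train], y[train], variables, config, w)
        for a_i, alpha in enumerate(alphas):
            pruned = _prune_at(subroot, alpha, w)
            for row in np.flatnonzero(test):
                risks[row, a_i] = pruned.predict_one(X[row], var_index)
    return risks


def _select_alpha(
    X: np.ndarray, y: np.ndarray, variables: Sequence[str], config: CartConfig,
    alphas: list[float],
) -> tuple[float, float]:
    """Choose the pruning complexity by pooled CV AUC with the one-SE
    parsimony rule.

    Among the candidate complexities, find the best pooled out-of-fold
    AUC, then return the largest alpha (smallest subtree) whose CV AUC is
    within one Hanley-McNeil standard error of that maximum.  Without the
    parsimony margin the full tree tends to win by a hair at large n —
    extra splits refine the inexact placement of true thresholds — and the
    selected model never shrinks toward the structural tree.
    Returns (alpha, cv_auc at that alpha)."""
    if len(alphas) == 1:
        return alphas[0], math.nan
    # evaluate at geometric midpoints of consecutive critical values, the
    # representative alpha of each interval
    mids = [0.0]
    for a, b in zip(alphas[:-1], alphas[1:]):
        mids.append(math.sqrt(max(a, _GAIN_EPS) * b) if b > 0 else 0.0)
    risks = _cv_risks_for_alphas(X, y, variables, config, mids)
    n1 = int(y.sum())
    n0 = len(y) - n1
    aucs: list[float] = []
    ses: list[float] = []
    for a_i in range(len(mids)):
        col = risks[:, a_i]
        if len(np.unique(col)) == 1:
            aucs.append(0.5)
            ses.append(0.0)
        else:
            res = roc_auc_with_ci(col, y)
            aucs.append(res.auc)
            ses.append(hanley_mcneil_se(res.auc, n1, n0))
    k_best = int(np.argmax(aucs))
    floor = aucs[k_best] - max(ses[k_best], _GAIN_EPS)
    chosen = k_best
    for k in range(len(mids)):
        if aucs[k] >= floor and mids[k] > mids[chosen]:
            chosen = k
    return mids[chosen], aucs[chosen]


def prune_tree(
    X: np.ndarray,
    y: Sequence[bool],
    variables: Sequence[str],
    config: CartConfig = CartConfig(),
    outcome_name: str = "outcome",
) -> TreeSpec:
    """Grow, then cost-complexity prune, selecting the subtree that
    maximizes the pooled cross-validated AUC (ties favor the smaller
    subtree).  Returns the pruned TreeSpec."""
    y = np.asarray(y, dtype=bool)
    X = np.asarray(X, dtype=float)
    _check_matrix(X, y, variables)
    weights = class_weights(y, config.class_weighting)
    root = _grow(X, y, variables, config, weights)
    if root.is_terminal:
        return _to_spec(root, outcome_name)
    alphas = _weakest_link_alphas(root, weights)
    alpha, _ = _select_alpha(X, y, variables, config, alphas)
    pruned = _prune_at(root, alpha, weights)
    return _to_spec(pruned, outcome_name)


def cross_validated_auc(
    X: np.ndarray,
    y: Sequence[bool],
    variables: Sequence[str],
    config: CartConfig = CartConfig(),
) -> float:
    """Summary k-fold cross-validated AUC of the full derivation procedure.

    Stratified folds seeded by ``cv_seed``; each fold's model is grown (and
    pruned, when configured) on the remaining folds; held-out episodes are
    assigned their terminal node's event rate as the risk; all out-of-fold
    risks are pooled into one AUC.
    """
    y = np.asarray(y, dtype=bool)
    X = np.asarray(X, dtype=float)
    _check_matrix(X, y, variables)
    folds = _stratified_folds(y, config.cv_folds, config.cv_seed)
    var_index = {v: j for j, v in enumerate(variables)}
    risks = np.empty(len(y))
    for f in range(config.cv_folds):
        train = folds != f
        w = class_weights(y[train], config.class_weighting)
        subroot = _grow(X[train], y[train], variables, config, w)
        if config.prune and not subroot.is_terminal:
            alphas = _weakest_link_alphas(subroot, w)
            sub_cfg = replace(config, cv_seed=config.cv_seed + 1 + f)
            try:
                alpha, _ = _select_alpha(
                    X[train], y[train], variables, sub_cfg, alphas
                )
            except CartError:  # too few events to stratify the inner CV
                alpha = 0.0
            subroot = _prune_at(subroot, alpha, w)
        for row in np.flatnonzero(~train):
            risks[row] = subroot.predict_one(X[row], var_index)
    if len(np.unique(risks)) == 1:
        return 0.5
    return roc_auc_with_ci(risks, y).auc


# ---------------------------------------------------------------------------
# DataFrame front door


def design_matrix(
    frame: pd.DataFrame, outcome: str, variables: Sequence[str] = PREDICTORS
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Extract (X, y, variables) from an analysis frame (see
    ``cohort.cohort_to_frame``)."""
    missing = [v for v in list(variables) + [outcome] if v not in frame.columns]
    if missing:
        raise CartError(f"frame missing column(s): {missing}")
    X = frame[list(variables)].to_numpy(dtype=float)
    y = frame[outcome].to_numpy(dtype=bool)
    return X, y, list(variables)


def derive_tree(
    frame: pd.DataFrame,
    outcome: str,
    config: CartConfig = CartConfig(),
    variables: Sequence[str] = PREDICTORS,
) -> tuple[TreeSpec, float]:
    """End-to-end derivation on an analysis frame: grow, prune (when
    configured), and compute the summary CV AUC.  Returns (tree, cv_auc)."""
    X, y, var = design_matrix(frame, outcome, variables)
    if config.prune:
        spec = prune_tree(X, y, var, config, outcome_name=outcome)
    else:
        spec = grow_tree(X, y, var, config, outcome_name=outcome)
    if int(y.sum()) >= config.cv_folds and 0 < int(y.sum()) < len(y):
        cv_auc = cross_validated_auc(X, y, var, config)
    else:
        cv_auc = math.nan
    return spec, cv_auc
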