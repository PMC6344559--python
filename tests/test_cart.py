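"""CART engine: impurity, split search, growth, pruning, cross-validation."""

import math
from dataclasses import replace

import numpy as np
import pytest

from sepsitree.cart import (
    CartConfig,
    CartError,
    best_split,
    class_weights,
    cross_validated_auc,
    derive_tree,
    design_matrix,
    gini_impurity,
    grow_tree,
    prune_tree,
)
from sepsitree.cohort import PREDICTORS, cohort_to_frame
from sepsitree.evaluation import roc_auc_with_ci
from sepsitree.risk_tree import SplitRule, TreeNode, TreeSpec, label_risk, validate_tree
from sepsitree.synth import default_paper_config, generate_cohort


class TestGini:
    @pytest.mark.parametrize(
        "n1, n0, expected",
        [(10, 10, 0.5), (0, 17, 0.0), (17, 0, 0.0), (30, 10, 0.375)],
    )
    def test_values(self, n1, n0, expected):
        assert gini_impurity(n1, n0) == pytest.approx(expected)

    def test_weighted_balance(self):
        # inverse-prevalence weights make any prevalence look balanced
        w1, w0 = class_weights(np.array([True] * 5 + [False] * 95), "balanced")
        assert gini_impurity(5, 95, w1, w0) == pytest.approx(0.5)

    def test_empty_node_error(self):
        with pytest.raises(CartError):
            gini_impurity(0, 0)


def _oracle_best_split(x, y, min_node, w1=1.0, w0=1.0):
    """Brute-force scan over all midpoints of one variable."""
    n = len(y)
    n1 = int(sum(y))
    if n1 in (0, n):
        return None
    parent = gini_impurity(n1, n - n1, w1, w0)
    wp = w1 * n1 + w0 * (n - n1)
    best = None
    for thr in sorted({(a + b) / 2 for a, b in zip(sorted(x)[:-1], sorted(x)[1:])
                       if a != b}):
        left = [yy for xx, yy in zip(x, y) if xx <= thr]
        right = [yy for xx, yy in zip(x, y) if xx > thr]
        if len(left) < min_node or len(right) < min_node:
            continue
        e_l, e_r = sum(left), sum(right)
        ml = w1 * e_l + w0 * (len(left) - e_l)
        mr = w1 * e_r + w0 * (len(right) - e_r)
        gain = parent - (
            ml * gini_impurity(e_l, len(left) - e_l, w1, w0)
            + mr * gini_impurity(e_r, len(right) - e_r, w1, w0)
        ) / wp
        if gain > 1e-12 and (best is None or gain > best[1] + 1e-12):
            best = (thr, gain)
    return best


class TestBestSplit:
    def test_pure_separation_midpoint(self):
        X = np.array([[1.0], [2.0], [10.0], [11.0]])
        y = np.array([0, 0, 1, 1], dtype=bool)
        cfg = CartConfig(min_node_size=1)
        found = best_split(X, y, ["il8"], cfg)
        assert found.variable == "il8"
        assert found.threshold == pytest.approx(6.0)

    def test_pure_node_returns_none(self):
        X = np.array([[1.0], [2.0], [3.0]])
        assert best_split(X, np.zeros(3, bool), ["il8"], CartConfig(min_node_size=1)) is None

    def test_constant_variable_returns_none(self):
        X = np.full((4, 1), 5.0)
        y = np.array([0, 1, 0, 1], dtype=bool)
        assert best_split(X, y, ["il8"], CartConfig(min_node_size=1)) is None

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_brute_force(self, seed):
        """Exhaustive-midpoint oracle on small random data, two predictors."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        X = rng.normal(size=(n, 2)).round(1)  # rounding forces ties
        y = rng.random(n) < 0.4
        cfg = CartConfig(min_node_size=2, class_weighting="none")
        found = best_split(X, y, ["il8", "ccl3"], cfg)
        oracles = {
            v: _oracle_best_split(X[:, j], y, 2) for j, v in enumerate(["il8", "ccl3"])
        }
        candidates = {v: o for v, o in oracles.items() if o is not None}
        if not candidates:
            assert found is None
            return
        best_gain = max(o[1] for o in candidates.values())
        assert found is not None
        assert found.gain == pytest.approx(best_gain)
        assert candidates[found.variable][1] == pytest.approx(found.gain)
        assert found.threshold == pytest.approx(candidates[found.variable][0])


def _conservation_ok(spec: TreeSpec) -> bool:
    for node in spec.nodes.values():
        if node.children is not None:
            l, r = (spec.nodes[c] for c in node.children)
            if l.n + r.n != node.n or l.n_event + r.n_event != node.n_event:
                return False
    return True


class TestGrowTree:
    def test_constant_outcome_single_node(self):
        X = np.random.default_rng(0).normal(size=(30, 2))
        spec = grow_tree(X, np.ones(30, bool), ["il8", "ccl3"], CartConfig(min_node_size=1))
        assert spec.n_terminals() == 1
        assert spec.root.event_rate == 1.0

    def test_depth_bound(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 3))
        y = rng.random(200) < 0.5
        spec = grow_tree(X, y, ["il8", "ccl3", "mmp8"], CartConfig(max_depth=1, min_node_size=5))
        assert spec.n_terminals() <= 2

    def test_partition_conservation(self, default_frame):
        X, y, var = design_matrix(default_frame, "deterioration")
        spec = grow_tree(X, y, var)
        assert _conservation_ok(spec)
        assert sum(t.n for t in spec.terminals()) == len(y)
        assert sum(t.n_event for t in spec.terminals()) == int(y.sum())

    def test_row_order_invariance(self, default_frame):
        X, y, var = design_matrix(default_frame, "deterioration")
        spec1 = grow_tree(X, y, var)
        rng = np.random.default_rng(2)
        perm = rng.permutation(len(y))
        spec2 = grow_tree(X[perm], y[perm], var)
        assert [
            (n.split.variable, round(n.split.threshold, 9))
            for n in spec1.nodes.values() if n.split
        ] == [
            (n.split.variable, round(n.split.threshold, 9))
            for n in spec2.nodes.values() if n.split
        ]

    def test_monotone_transform_invariance(self, default_frame):
        """Log-transforming a predictor preserves the tree's structure: same
        split variables in the same places, same node counts."""
        X, y, var = design_matrix(default_frame, "deterioration")
        Xlog = X.copy()
        Xlog[:, 0] = np.log(Xlog[:, 0] + 1e-9)
        s1 = grow_tree(X, y, var)
        s2 = grow_tree(Xlog, y, var)
        shape1 = [(n.node_id, n.n, n.n_event,
                   None if n.split is None else n.split.variable)
                  for n in s1.nodes.values()]
        shape2 = [(n.node_id, n.n, n.n_event,
                   None if n.split is None else n.split.variable)
                  for n in s2.nodes.values()]
        assert shape1 == shape2


def _two_split_truth() -> TreeSpec:
    nodes = {
        "1": TreeNode("1", n=2000, n_event=300,
                      split=SplitRule("il8", 1070.0), children=("2", "3")),
        "2": TreeNode("2", n=1700, n_event=144,
                      split=SplitRule("ccl3", 60.0), children=("4", "5")),
        "3": TreeNode("3", n=300, n_event=156),
        "4": TreeNode("4", n=1200, n_event=24),
        "5": TreeNode("5", n=500, n_event=120),
    }
    spec = TreeSpec("deterioration", 0.15, nodes, "1")
    label_risk(spec)
    validate_tree(spec)
    return spec


class TestPrune:
    def test_single_node_unchanged(self):
        X = np.random.default_rng(0).normal(size=(50, 2))
        y = np.zeros(50, bool)
        y[:5] = True
        spec = prune_tree(X, y, ["il8", "ccl3"], CartConfig(min_node_size=40))
        assert spec.n_terminals() == 1

    def test_never_more_terminals_than_grown(self, default_frame):
        X, y, var = design_matrix(default_frame, "deterioration")
        grown = grow_tree(X, y, var)
        pruned = prune_tree(X, y, var)
        assert pruned.n_terminals() <= grown.n_terminals()
        assert _conservation_ok(pruned)

    def test_recovers_two_split_truth_size(self):
        """Tree-mode cohorts with a 2-split embedded truth: the pruned tree
        has 3 +/- 1 terminal nodes in the bulk of replicates."""
        terms = []
        for seed in range(5):
            cfg = replace(
                default_paper_config(seed=seed), mode="tree",
                truth_tree=_two_split_truth(), n_episodes=4000,
                n_subjects=4000, n_repeat_subjects=0,
            )
            f = cohort_to_frame(generate_cohort(cfg))
            X, y, var = design_matrix(f, "deterioration")
            terms.append(prune_tree(X, y, var, CartConfig(cv_seed=seed)).n_terminals())
        assert 2 <= float(np.median(terms)) <= 4
        assert sum(2 <= t <= 4 for t in terms) >= 4


class TestCrossValidatedAuc:
    def test_perfectly_separable(self):
        rng = np.random.default_rng(0)
        X = rng.lognormal(math.log(250), 1.5, size=(1000, len(PREDICTORS)))
        y = X[:, 0] > 1070.0
        auc = cross_validated_auc(X, y, list(PREDICTORS), CartConfig())
        assert auc >= 0.98

    def test_optimism_of_resubstitution(self):
        """Out-of-fold AUC does not beat resubstitution by more than noise."""
        for seed in (0, 1, 2):
            cfg = replace(
                default_paper_config(seed=seed), mode="tree",
                truth_tree=_two_split_truth(), n_episodes=800,
                n_subjects=800, n_repeat_subjects=0,
            )
            f = cohort_to_frame(generate_cohort(cfg))
            X, y, var = design_matrix(f, "deterioration")
            cart_cfg = CartConfig(cv_seed=seed)
            spec = prune_tree(X, y, var, cart_cfg)
            # resubstitution risks: each row's terminal event rate
            risks = _predict(spec, X, var)
            resub = roc_auc_with_ci(risks, y).auc
            cv = cross_validated_auc(X, y, var, cart_cfg)
            assert cv <= resub + 0.02

    def test_too_few_events_raises(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 2))
        y = np.zeros(100, bool)
        y[:5] = True
        with pytest.raises(CartError, match="stratify"):
            cross_validated_auc(X, y, ["il8", "ccl3"], CartConfig(cv_folds=10))


def _predict(spec: TreeSpec, X: np.ndarray, variables) -> np.ndarray:
    idx = {v: j for j, v in enumerate(variables)}
    out = np.empty(len(X))
    for i, row in enumerate(X):
        node = spec.root
        while not node.is_terminal:
            v = row[idx[node.split.variable]]
            node = spec.nodes[node.children[0] if v <= node.split.threshold
                              else node.children[1]]
        out[i] = node.event_rate
    return out


def test_derive_tree_default_complexity(default_frame):
    """On a default 400-episode cohort the pruned deterioration tree stays
    within the intended complexity envelope (<= 5 terminal nodes)."""
    spec, cv_auc = derive_tree(default_frame, "deterioration", CartConfig(cv_seed=1))
    assert spec.n_terminals() <= 5
    assert 0.0 <= cv_auc <= 1.0
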