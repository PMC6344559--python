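"""Portable decision-tree risk models and their application engine.

A :class:`TreeSpec` is a self-contained binary decision tree over the seven
candidate predictors (five serum biomarkers, age, platelet count).  Each
terminal node carries the training counts and event rate observed there;
the event rate serves as the risk probability assigned to any episode that
lands in the node, and a terminal is labeled *high* risk exactly when its
event rate exceeds the cohort baseline rate.

The split convention is fixed globally: an episode goes to the *left* child
when its value is <= the threshold and to the *right* child when it is
strictly greater, so "biomarker > cutpoint" always describes the right
(typically higher-risk) branch.

Specs serialize to a small JSON document (schema shipped as package data in
``data/treespec.schema.json``) so that externally published models — e.g.
user-transcribed PERSEVERE cutpoints — can be applied with the same engine.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

from .cohort import PREDICTORS, Episode

RISK_LOW = "low"
RISK_HIGH = "high"

_RATE_TOL = 1e-9


class TreeValidationError(ValueError):
    """The tree document violates a structural invariant; lists all violations."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("invalid tree spec: " + "; ".join(violations))


class MissingPredictorError(ValueError):
    """An episode lacks a value for a predictor the tree consults."""

    def __init__(self, variable: str, node_id: str):
        self.variable = variable
        self.node_id = node_id
        super().__init__(
            f"episode is missing predictor {variable!r} consulted at node {node_id!r}"
        )


@dataclass(frozen=True)
class SplitRule:
    """Binary partition: left iff value <= threshold, right iff value > threshold."""

    variable: str
    threshold: float


@dataclass
class TreeNode:
    node_id: str
    n: int
    n_event: int
    split: Optional[SplitRule] = None
    children: Optional[tuple[str, str]] = None  # (left, right)
    risk_label: Optional[str] = None  # terminals only

    @property
    def is_terminal(self) -> bool:
        return self.children is None

    @property
    def event_rate(self) -> float:
        return self.n_event / self.n


@dataclass
class TreeSpec:
    """A validated decision-tree risk model.

    ``baseline_rate`` is the event prevalence of the derivation cohort; it
    anchors the low/high risk labels of the terminal nodes.
    """

    outcome_name: str
    baseline_rate: float
    nodes: dict[str, TreeNode] = field(default_factory=dict)
    root_id: str = "1"

    @property
    def root(self) -> TreeNode:
        return self.nodes[self.root_id]

    def terminals(self) -> list[TreeNode]:
        return [n for n in self.nodes.values() if n.is_terminal]

    def n_terminals(self) -> int:
        return len(self.terminals())

    def variables_used(self) -> set[str]:
        return {n.split.variable for n in self.nodes.values() if n.split is not None}


@dataclass(frozen=True)
class RiskAssignment:
    """Outcome of pushing one episode through a tree."""

    subject_id: str
    episode_id: str
    terminal_node_id: str
    risk: float  # the terminal's event rate, exactly
    risk_class: str  # "low" | "high"


# ---------------------------------------------------------------------------
# Validation


def validate_tree(spec: TreeSpec) -> None:
    """Check every structural invariant; raise with the full violation list."""
    errs: list[str] = []
    nodes = spec.nodes
    if spec.root_id not in nodes:
        raise TreeValidationError([f"root node {spec.root_id!r} not present"])
    if not (0.0 <= spec.baseline_rate <= 1.0):
        errs.append(f"baseline_rate {spec.baseline_rate} outside [0, 1]")

    child_refs: list[str] = []
    for node in nodes.values():
        if node.n <= 0:
            errs.append(f"node {node.node_id}: n must be > 0")
        if not (0 <= node.n_event <= node.n):
            errs.append(f"node {node.node_id}: n_event outside [0, n]")
        if (node.split is None) != (node.children is None):
            errs.append(f"node {node.node_id}: split and children must co-occur")
        if node.children is not None:
            if len(node.children) != 2:
                errs.append(f"node {node.node_id}: must have exactly 2 children")
                continue
            child_refs.extend(node.children)
            missing = [c for c in node.children if c not in nodes]
            if missing:
                errs.append(f"node {node.node_id}: unknown child id(s) {missing}")
                continue
            left, right = (nodes[c] for c in node.children)
            if left.n + right.n != node.n:
                errs.append(
                    f"node {node.node_id}: children n {left.n}+{right.n} != {node.n}"
                )
            if left.n_event + right.n_event != node.n_event:
                errs.append(
                    f"node {node.node_id}: children n_event "
                    f"{left.n_event}+{right.n_event} != {node.n_event}"
                )
        if node.split is not None:
            if node.split.variable not in PREDICTORS:
                errs.append(
                    f"node {node.node_id}: unknown predictor {node.split.variable!r}"
                )
            if not math.isfinite(node.split.threshold):
                errs.append(f"node {node.node_id}: non-finite threshold")
        if node.is_terminal:
            if node.risk_label not in (RISK_LOW, RISK_HIGH):
                errs.append(f"terminal {node.node_id}: risk_label must be low/high")
            elif node.n > 0:
                expect = RISK_HIGH if node.event_rate > spec.baseline_rate else RISK_LOW
                if node.risk_label != expect:
                    errs.append(
                        f"terminal {node.node_id}: risk_label {node.risk_label!r} "
                        f"inconsistent with rate {node.event_rate:.4g} vs baseline "
                        f"{spec.baseline_rate:.4g}"
                    )

    if len(child_refs) != len(set(child_refs)):
        errs.append("a node is referenced as a child more than once")
    roots = set(nodes) - set(child_refs)
    if roots != {spec.root_id}:
        errs.append(
            f"expected exactly one root {spec.root_id!r}, found unreferenced nodes "
            f"{sorted(roots)}"
        )
    # reachability doubles as the acyclicity check: every node must be
    # reached exactly once walking down from the root
    seen: set[str] = set()
    stack = [spec.root_id]
    while stack:
        nid = stack.pop()
        if nid in seen:
            errs.append(f"cycle detected at node {nid}")
            break
        seen.add(nid)
        node = nodes.get(nid)
        if node is not None and node.children is not None:
            stack.extend(c for c in node.children if c in nodes)
    orphans = set(nodes) - seen
    if orphans and not errs:
        errs.append(f"orphan node(s) unreachable from root: {sorted(orphans)}")

    if errs:
        raise TreeValidationError(errs)


def label_risk(spec: TreeSpec) -> TreeSpec:
    """(Re)assign terminal risk labels from the baseline-rate rule in place."""
    for node in spec.nodes.values():
        if node.is_terminal:
            node.risk_label = (
                RISK_HIGH if node.event_rate > spec.baseline_rate else RISK_LOW
            )
    return spec


# ---------------------------------------------------------------------------
# Application


def apply_tree(spec: TreeSpec, episode: Episode) -> RiskAssignment:
    """Descend from the root (left iff value <= threshold) and return the
    terminal node id, its event rate as the risk, and the low/high label.

    A missing value on a consulted predictor is a hard
    :class:`MissingPredictorError`; no imputation or surrogate splits.
    """
    node = spec.root
    while not node.is_terminal:
        value = episode.predictor(node.split.variable)
        if value is None:
            raise MissingPredictorError(node.split.variable, node.node_id)
        nxt = node.children[0] if value <= node.split.threshold else node.children[1]
        node = spec.nodes[nxt]
    return RiskAssignment(
        subject_id=episode.subject_id,
        episode_id=episode.episode_id,
        terminal_node_id=node.node_id,
        risk=node.event_rate,
        risk_class=node.risk_label if node.risk_label is not None else (
            RISK_HIGH if node.event_rate > spec.baseline_rate else RISK_LOW
        ),
    )


def classify_high_risk(spec: TreeSpec, episode: Episode) -> bool:
    """True iff the episode lands in a high-risk terminal node."""
    return apply_tree(spec, episode).risk_class == RISK_HIGH


# ---------------------------------------------------------------------------
# Serialization


def to_json(spec: TreeSpec, *, indent: int = 2) -> str:
    """Serialize a TreeSpec to its JSON document."""
    node_docs = []
    for node in spec.nodes.values():
        doc: dict = {"id": node.node_id, "n": node.n, "n_event": node.n_event,
                     "event_rate": node.event_rate}
        if node.split is not None:
            doc["variable"] = node.split.variable
            doc["threshold"] = node.split.threshold
        if node.children is not None:
            doc["children"] = list(node.children)
        if node.risk_label is not None:
            doc["risk_label"] = node.risk_label
        node_docs.append(doc)
    return json.dumps(
        {
            "outcome_name": spec.outcome_name,
            "baseline_rate": spec.baseline_rate,
            "root": spec.root_id,
            "nodes": node_docs,
        },
        indent=indent,
    )


def from_json(text: str) -> TreeSpec:
    """Parse and fully validate a TreeSpec JSON document."""
    doc = json.loads(text)
    errs: list[str] = []
    for key in ("outcome_name", "baseline_rate", "nodes"):
        if key not in doc:
            errs.append(f"missing top-level key {key!r}")
    if errs:
        raise TreeValidationError(errs)
    nodes: dict[str, TreeNode] = {}
    for nd in doc["nodes"]:
        nid = str(nd["id"])
        split = None
        if "variable" in nd or "threshold" in nd:
            if not ("variable" in nd and "threshold" in nd):
                errs.append(f"node {nid}: variable and threshold must co-occur")
                continue
            split = SplitRule(str(nd["variable"]), float(nd["threshold"]))
        children = tuple(str(c) for c in nd["children"]) if "children" in nd else None
        node = TreeNode(
            node_id=nid,
            n=int(nd["n"]),
            n_event=int(nd["n_event"]),
            split=split,
            children=children,
            risk_label=nd.get("risk_label"),
        )
        if "event_rate" in nd and node.n > 0:
            if abs(float(nd["event_rate"]) - node.event_rate) > _RATE_TOL:
                errs.append(
                    f"node {nid}: event_rate {nd['event_rate']} != n_event/n "
                    f"{node.event_rate}"
                )
        nodes[nid] = node
    if errs:
        raise TreeValidationError(errs)
    root_id = str(doc.get("root", "1"))
    spec = TreeSpec(
        outcome_name=str(doc["outcome_name"]),
        baseline_rate=float(doc["baseline_rate"]),
        nodes=nodes,
        root_id=root_id,
    )
    validate_tree(spec)
    return spec


def load_tree(path) -> TreeSpec:
    with open(path, encoding="utf-8") as fh:
        return from_json(fh.read())


def save_tree(spec: TreeSpec, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(to_json(spec))
        fh.write("\n")


# ---------------------------------------------------------------------------
# Construction helpers


def single_split_tree(
    variable: str,
    threshold: float,
    *,
    outcome_name: str,
    baseline_rate: float,
    left_rate: float,
    right_rate: float,
    n_left: int = 1000,
    n_right: int = 1000,
) -> TreeSpec:
    """Build a one-split tree from node event rates.

    Convenient for embedding a known truth tree in simulations and for
    expressing a published single-cutpoint rule.  Counts are synthesized to
    be consistent with the requested rates (rounded to whole events).
    """
    e_left = round(left_rate * n_left)
    e_right = round(right_rate * n_right)
    nodes = {
        "1": TreeNode("1", n=n_left + n_right, n_event=e_left + e_right,
                      split=SplitRule(variable, threshold), children=("2", "3")),
        "2": TreeNode("2", n=n_left, n_event=e_left),
        "3": TreeNode("3", n=n_right, n_event=e_right),
    }
    spec = TreeSpec(outcome_name=outcome_name, baseline_rate=baseline_rate,
                    nodes=nodes, root_id="1")
    label_risk(spec)
    validate_tree(spec)
    return spec


def render_rules(spec: TreeSpec) -> str:
    """Human-readable indented rule listing of the tree."""
    lines: list[str] = []

    def walk(nid: str, depth: int, prefix: str) -> None:
        node = spec.nodes[nid]
        pad = "  " * depth
        stats = f"n={node.n}, events={node.n_event} ({100 * node.event_rate:.1f}%)"
        if node.is_terminal:
            lines.append(f"{pad}{prefix}terminal node {nid} [{node.risk_label} risk] {stats}")
        else:
            lines.append(f"{pad}{prefix}node {nid} {stats}")
            v, t = node.split.variable, node.split.threshold
            walk(node.children[0], depth + 1, f"if {v} <= {t:g}: ")
            walk(node.children[1], depth + 1, f"if {v} > {t:g}: ")

    walk(spec.root_id, 0, "")
    return "\n".join(lines)
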