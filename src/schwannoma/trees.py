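"""Binary decision trees with explicit missing-value routing.

Each internal node holds a rule ``variable <op> threshold`` with
``op in {">=", "<", "=="}`` and two children: the *true* child taken when the
rule holds and the *false* child otherwise.  A node may additionally route
missing inputs (``missing_to``) down one of its branches; a node without a
missing route raises :class:`RoutingError` when asked to split on a missing
value — erring is safer than guessing.

The module also ships the two reference trees of the vestibular-schwannoma
decision-support rule base (the static per-checkup tree over the expert CBR
variables, and the two-level longitudinal tree over Koos/size dynamics), and
a small greedy learner (chi-square or Gini splits) so the same representation
can be re-derived from data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

YES = "Yes"
NO = "No"

_OPS = (">=", "<", "==")


class RoutingError(ValueError):
    """A missing value reached a node with no missing route."""


@dataclass(frozen=True)
class DecisionNode:
    """One node: either an internal rule node or a leaf.

    ``missing_to`` is ``"true"``, ``"false"`` or ``None``; it names the branch
    taken when the rule's variable is missing.
    """

    node_id: int
    variable: str | None = None
    op: str | None = None
    threshold: float | None = None
    true_child: int | None = None
    false_child: int | None = None
    missing_to: str | None = None
    leaf_decision: str | None = None
    n_samples: int | None = None

    def __post_init__(self):
        internal = self.true_child is not None and self.false_child is not None
        leaf = self.leaf_decision is not None
        if internal == leaf:
            raise ValueError(
                f"node {self.node_id}: must be exactly one of internal or leaf"
            )
        if internal:
            if self.variable is None or self.op not in _OPS or self.threshold is None:
                raise ValueError(f"node {self.node_id}: malformed rule")
            if self.missing_to not in (None, "true", "false"):
                raise ValueError(f"node {self.node_id}: bad missing_to {self.missing_to!r}")
        elif self.leaf_decision not in (YES, NO):
            raise ValueError(f"node {self.node_id}: leaf decision must be Yes/No")

    @property
    def is_leaf(self) -> bool:
        return self.leaf_decision is not None

    def evaluate(self, value: float) -> bool:
        if self.op == ">=":
            return value >= self.threshold
        if self.op == "<":
            return value < self.threshold
        return value == self.threshold

    def rule_text(self) -> str:
        if self.is_leaf:
            return self.leaf_decision
        na = " or N/A" if self.missing_to == "true" else ""
        return f"{self.variable} {self.op.replace('==', '=')} {self.threshold:g}{na}"


@dataclass(frozen=True)
class InferenceTrace:
    """Root-to-leaf path taken for one feature vector."""

    path: tuple[int, ...]
    decision: str
    inputs_used: frozenset[str]


class DecisionTree:
    """Rooted binary tree over uniquely numbered nodes."""

    def __init__(self, nodes: Iterable[DecisionNode], root_id: int | None = None):
        nodes = list(nodes)
        self.nodes: dict[int, DecisionNode] = {}
        for n in nodes:
            if n.node_id in self.nodes:
                raise ValueError(f"duplicate node_id {n.node_id}")
            self.nodes[n.node_id] = n
        children = [c for n in nodes if not n.is_leaf for c in (n.true_child, n.false_child)]
        if len(children) != len(set(children)):
            raise ValueError("a node has more than one parent")
        for c in children:
            if c not in self.nodes:
                raise ValueError(f"dangling child id {c}")
        roots = set(self.nodes) - set(children)
        if root_id is None:
            if len(roots) != 1:
                raise ValueError(f"tree must have exactly one root, found {sorted(roots)}")
            root_id = roots.pop()
        elif root_id not in roots:
            raise ValueError(f"declared root {root_id} has a parent or is unknown")
        self.root_id = root_id
        self._check_acyclic()

    def _check_acyclic(self):
        seen: set[int] = set()
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise ValueError(f"cycle through node {nid}")
            seen.add(nid)
            n = self.nodes[nid]
            if not n.is_leaf:
                stack += [n.true_child, n.false_child]
        if seen != set(self.nodes):
            raise ValueError("unreachable nodes present")

    @property
    def root(self) -> DecisionNode:
        return self.nodes[self.root_id]

    def leaves(self) -> list[DecisionNode]:
        return [n for n in self.nodes.values() if n.is_leaf]

    def variables(self) -> set[str]:
        return {n.variable for n in self.nodes.values() if not n.is_leaf}

    def __len__(self) -> int:
        return len(self.nodes)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        rows = []
        for nid in sorted(self.nodes):
            n = self.nodes[nid]
            rows.append({k: v for k, v in n.__dict__.items() if v is not None})
        return json.dumps({"root": self.root_id, "nodes": rows}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DecisionTree":
        doc = json.loads(text)
        nodes = [DecisionNode(**row) for row in doc["nodes"]]
        return cls(nodes, root_id=doc.get("root"))

    def to_dot(self, title: str = "tree") -> str:
        """Graphviz DOT rendering for figures."""
        lines = [f'digraph "{title}" {{', "  node [shape=box, fontname=Helvetica];"]
        for nid in sorted(self.nodes):
            n = self.nodes[nid]
            label = f"{nid}: {n.rule_text()}"
            if n.n_samples is not None:
                label += f"\\nn={n.n_samples}"
            shape = ', style=filled, fillcolor="#e8f0fe"' if n.is_leaf else ""
            lines.append(f'  {nid} [label="{label}"{shape}];')
        for nid in sorted(self.nodes):
            n = self.nodes[nid]
            if not n.is_leaf:
                lines.append(f'  {nid} -> {n.true_child} [label="yes"];')
                lines.append(f'  {nid} -> {n.false_child} [label="no"];')
        lines.append("}")
        return "\n".join(lines)


def _missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def route(tree: DecisionTree, features: Mapping[str, float | None]) -> InferenceTrace:
    """Deterministic descent from the root; returns the visited path and decision.

    Only variables named by the rules along the path are ever inspected.
    """
    path = [tree.root_id]
    used: set[str] = set()
    node = tree.root
    while not node.is_leaf:
        value = features.get(node.variable)
        used.add(node.variable)
        if _missing(value):
            if node.missing_to is None:
                raise RoutingError(
                    f"missing value for {node.variable!r} at node {node.node_id} "
                    "which has no missing route"
                )
            branch = node.missing_to == "true"
        else:
            branch = node.evaluate(float(value))
        nxt = node.true_child if branch else node.false_child
        path.append(nxt)
        node = tree.nodes[nxt]
    return InferenceTrace(path=tuple(path), decision=node.leaf_decision,
                          inputs_used=frozenset(used))


# ---------------------------------------------------------------------------
# reference trees
# ---------------------------------------------------------------------------

def cbr_reference_tree() -> DecisionTree:
    """The 13-node static (per-checkup) reference tree.

    Rules read "variable >= threshold [or N/A]" with the true branch taken when
    the comparison (or the missing-value clause) holds; Koos is tested for
    exact equality.  Sample counts are annotations from the source cohort.
    """
    N = DecisionNode
    return DecisionTree([
        N(1, "PTA_VS_SR8", ">=", 2.3, true_child=3, false_child=2, missing_to="true", n_samples=184),
        N(2, "SRT", ">=", 27.5, true_child=5, false_child=4, missing_to="true", n_samples=61),
        N(3, "PTA_H_SR8", ">=", 6.7, true_child=7, false_child=6, n_samples=123),
        N(4, leaf_decision=NO, n_samples=9),
        N(5, leaf_decision=YES, n_samples=52),
        N(6, "PTA_D_AR4", ">=", 18.1, true_child=9, false_child=8, missing_to="true", n_samples=86),
        N(7, leaf_decision=NO, n_samples=37),
        N(8, leaf_decision=YES, n_samples=17),
        N(9, "PTA_VS_SR8", ">=", 7.1, true_child=11, false_child=10, n_samples=69),
        N(10, leaf_decision=NO, n_samples=39),
        N(11, "Koos", "==", 2.0, true_child=13, false_child=12, n_samples=30),
        N(12, leaf_decision=NO, n_samples=18),
        N(13, leaf_decision=YES, n_samples=12),
    ])


def pda_reference_tree() -> DecisionTree:
    """The 5-node longitudinal reference tree over Koos/size dynamics.

    Any change of Koos grade since the previous checkup recommends active
    treatment; with Koos unchanged, a tumor-size slope of at least
    0.0064 mm/day (about 2.3 mm/year) recommends it.
    """
    N = DecisionNode
    return DecisionTree([
        N(1, "Koos_LD", "<", 0.01, true_child=2, false_child=3, n_samples=42),
        N(2, "Size_SC", "<", 0.0064, true_child=4, false_child=5, n_samples=31),
        N(3, leaf_decision=YES, n_samples=11),
        N(4, leaf_decision=NO, n_samples=24),
        N(5, leaf_decision=YES, n_samples=7),
    ])


# ---------------------------------------------------------------------------
# greedy induction
# ---------------------------------------------------------------------------

def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p ** 2).sum())


def _split_score(y_true_side: np.ndarray, y_false_side: np.ndarray, criterion: str) -> float:
    """Higher is better.  Gini: weighted impurity decrease; chi-square: the
    2x2 association statistic (no continuity correction)."""
    n_t, n_f = len(y_true_side), len(y_false_side)
    n = n_t + n_f
    ct = np.array([np.bincount(y_true_side, minlength=2),
                   np.bincount(y_false_side, minlength=2)], dtype=float)
    if criterion == "gini":
        parent = _gini(ct.sum(axis=0))
        child = (n_t / n) * _gini(ct[0]) + (n_f / n) * _gini(ct[1])
        return parent - child
    if criterion == "chi_square":
        row = ct.sum(axis=1, keepdims=True)
        col = ct.sum(axis=0, keepdims=True)
        expected = row @ col / n
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(expected > 0, (ct - expected) ** 2 / expected, 0.0)
        return float(terms.sum())
    raise ValueError(f"unknown criterion {criterion!r}")


def learn_tree(
    dataset: pd.DataFrame,
    target: str,
    criterion: str = "chi_square",
    max_depth: int | None = None,
    min_leaf: int = 1,
    seed: int = 0,
    positive: str | int = "Active",
) -> DecisionTree:
    """Greedy top-down induction of a :class:`DecisionTree`.

    Candidate thresholds are midpoints between consecutive observed values;
    rows with a missing split variable follow the branch holding the majority
    of the non-missing rows (recorded as the node's ``missing_to``).  The
    procedure is deterministic: ties break by feature column order, then by
    lower threshold.  Leaves predict Yes for the positive (active-treatment)
    class majority.
    """
    features = [c for c in dataset.columns if c != target]
    X = dataset[features].to_numpy(dtype=float)
    y_raw = dataset[target].to_numpy()
    y = np.asarray([1 if v == positive or v == 1 else 0 for v in y_raw], dtype=int)

    nodes: list[DecisionNode] = []
    counter = {"next": 1}

    def grow(idx: np.ndarray, depth: int) -> int:
        nid = counter["next"]
        counter["next"] += 1
        ysub = y[idx]
        n_pos = int(ysub.sum())
        majority = YES if n_pos * 2 >= len(ysub) else NO
        if (
            len(np.unique(ysub)) == 1
            or (max_depth is not None and depth >= max_depth)
            or len(idx) < 2 * min_leaf
        ):
            nodes.append(DecisionNode(nid, leaf_decision=majority, n_samples=len(idx)))
            return nid

        best = None  # (score, col, threshold, mask_true, missing_branch)
        for col, name in enumerate(features):
            xv = X[idx, col]
            present = ~np.isnan(xv)
            vals = np.unique(xv[present])
            if len(vals) < 2:
                continue
            for thr in (vals[:-1] + vals[1:]) / 2.0:
                true_mask = present & (xv >= thr)
                false_mask = present & ~true_mask
                # missing rows go with the majority branch
                miss_to_true = true_mask.sum() >= false_mask.sum()
                if miss_to_true:
                    true_mask = true_mask | ~present
                else:
                    false_mask = false_mask | ~present
                if true_mask.sum() < min_leaf or false_mask.sum() < min_leaf:
                    continue
                score = _split_score(ysub[true_mask], ysub[false_mask], criterion)
                key = (-score, col, thr)
                if best is None or key < best[0]:
                    best = (key, col, thr, true_mask, miss_to_true)
        if best is None or -best[0][0] <= 1e-12:  # no split improves on a leaf
            nodes.append(DecisionNode(nid, leaf_decision=majority, n_samples=len(idx)))
            return nid

        _, col, thr, true_mask, miss_to_true = best
        placeholder = len(nodes)
        nodes.append(None)  # reserve position; filled after children exist
        t_id = grow(idx[true_mask], depth + 1)
        f_id = grow(idx[~true_mask], depth + 1)
        nodes[placeholder] = DecisionNode(
            nid, features[col], ">=", float(thr),
            true_child=t_id, false_child=f_id,
            missing_to="true" if miss_to_true else "false",
            n_samples=len(idx),
        )
        return nid

    grow(np.arange(len(dataset)), 0)
    return DecisionTree(nodes)


def tree_predictions(tree: DecisionTree, dataset: pd.DataFrame, target: str | None = None) -> list[str]:
    """Route every row of a feature table; returns Yes/No per row."""
    cols = [c for c in dataset.columns if c != target]
    return [route(tree, row.to_dict()).decision for _, row in dataset[cols].iterrows()]


def learn_tree_validated(
    train: pd.DataFrame,
    valid: pd.DataFrame,
    target: str,
    criterion: str = "chi_square",
    depths: Sequence[int] = (1, 2, 3, 4),
    min_leaf: int = 10,
    seed: int = 0,
    positive: str | int = "Active",
) -> DecisionTree:
    """Fit one tree per candidate depth on ``train``; keep the depth with the
    best validation accuracy (ties favour the shallower tree)."""
    y_valid = [YES if v == positive or v == 1 else NO for v in valid[target]]
    best: tuple[float, int, DecisionTree] | None = None
    for depth in depths:
        tree = learn_tree(train, target, criterion=criterion, max_depth=depth,
                          min_leaf=min_leaf, seed=seed, positive=positive)
        preds = tree_predictions(tree, valid, target)
        acc = float(np.mean([p == y for p, y in zip(preds, y_valid)]))
        if best is None or acc > best[0]:
            best = (acc, depth, tree)
    return best[2]
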