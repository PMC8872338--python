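"""Generic decision-tree representation and expected-value evaluation.

A :class:`DecisionTree` is a decision node over strategies whose subtrees
contain only chance and terminal nodes.  Payoffs are two-component
(cost in AUD, effectiveness on a proportion scale) and accrue on nodes;
costs are discounted to present value at evaluation time using the node's
accrual time in fractional years.

Subtrees may share child Node objects (the graph is a rooted DAG): the
surveillance model uses this to keep the per-visit confusion chain linear
in the number of scheduled visits.  Evaluation memoizes on node identity,
so shared structure is evaluated once.  :func:`enumerate_paths` expands
every distinct root-to-leaf path and is intended as a brute-force oracle
on small trees.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

#: absolute tolerance for chance-node branch probabilities summing to 1
PROB_TOL = 1e-9

DECISION = "decision"
CHANCE = "chance"
TERMINAL = "terminal"


@dataclass
class Payoff:
    """Two-component payoff accrued on traversing a node."""

    cost: float = 0.0
    effect: float = 0.0


@dataclass(eq=False)
class Node:
    """A decision, chance, or terminal node.

    ``children`` is a list of ``(branch_probability, Node)`` pairs for
    chance nodes and a list of ``Node`` for decision nodes; terminal nodes
    have no children.  ``counts`` optionally carries (TP, FP, TN, FN)
    tally increments used by the surveillance model.
    """

    kind: str
    label: str = ""
    payoff: Payoff = field(default_factory=Payoff)
    accrual_time: float = 0.0
    children: list = field(default_factory=list)
    counts: tuple[float, float, float, float] | None = None


@dataclass
class DecisionTree:
    """A decision node over strategies; the evaluable model."""

    root: Node
    strategy_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.strategy_labels and self.root.kind == DECISION:
            self.strategy_labels = [c.label for c in self.root.children]


class StrategyValue(NamedTuple):
    cost: float
    effect: float
    counts: tuple[float, float, float, float]


class PathRecord(NamedTuple):
    strategy: str
    probability: float
    cost: float  # undiscounted sum of payoff costs along the path
    effect: float
    times: tuple[float, ...]  # accrual time of each payoff along the path


def _iter_branches(node: Node) -> Iterable[tuple[float | None, Node]]:
    if node.kind == CHANCE:
        for prob, child in node.children:
            yield prob, child
    elif node.kind == DECISION:
        for child in node.children:
            yield None, child


def validate_tree(tree: DecisionTree) -> list[str]:
    """Check every structural invariant; return a description per violation.

    Validation never raises.  An empty list means the tree is valid.
    """
    violations: list[str] = []
    on_path: set[int] = set()
    seen: set[int] = set()

    def visit(node: Node, is_root: bool) -> None:
        nid = id(node)
        if nid in on_path:
            violations.append(f"node '{node.label}': cycle detected")
            return
        if node.kind == DECISION and not is_root:
            violations.append(
                f"node '{node.label}': decision node below the root"
            )
        if node.kind == TERMINAL and node.children:
            violations.append(f"node '{node.label}': terminal node has children")
        if node.kind not in (DECISION, CHANCE, TERMINAL):
            violations.append(f"node '{node.label}': unknown kind {node.kind!r}")
        if not math.isfinite(node.payoff.effect):
            violations.append(f"node '{node.label}': non-finite effect")
        if node.payoff.cost < 0:
            violations.append(f"node '{node.label}': negative cost")
        if node.kind == CHANCE:
            if not node.children:
                violations.append(f"node '{node.label}': chance node has no branches")
            else:
                total = 0.0
                for prob, _ in node.children:
                    if not (0.0 <= prob <= 1.0):
                        violations.append(
                            f"node '{node.label}': branch probability {prob} "
                            "outside [0, 1]"
                        )
                    total += prob
                if abs(total - 1.0) > PROB_TOL:
                    violations.append(
                        f"node '{node.label}': branch probabilities sum to "
                        f"{total!r}, not 1"
                    )
        if nid in seen:
            return  # shared subtree already checked
        seen.add(nid)
        on_path.add(nid)
        for _, child in _iter_branches(node):
            visit(child, is_root=False)
        on_path.discard(nid)

    visit(tree.root, is_root=True)
    return violations


def _require_valid(tree: DecisionTree) -> None:
    violations = validate_tree(tree)
    if violations:
        raise ValueError(f"invalid decision tree: {violations[0]}")


def evaluate_node(
    node: Node, discount_rate: float = 0.0, discount_effects: bool = False
) -> StrategyValue:
    """Expected (discounted cost, effect, TP/FP/TN/FN tallies) of a subtree.

    Costs are discounted by ``1/(1+r)^t`` with ``t`` the payoff's accrual
    time in fractional years; effects are left undiscounted unless
    ``discount_effects`` is set.
    """
    memo: dict[int, tuple[float, float, np.ndarray]] = {}

    def value(n: Node) -> tuple[float, float, np.ndarray]:
        cached = memo.get(id(n))
        if cached is not None:
            return cached
        df = (1.0 + discount_rate) ** (-n.accrual_time)
        cost = n.payoff.cost * df
        effect = n.payoff.effect * (df if discount_effects else 1.0)
        counts = np.asarray(n.counts, dtype=float) if n.counts else np.zeros(4)
        for prob, child in _iter_branches(n):
            c_cost, c_eff, c_counts = value(child)
            cost += prob * c_cost
            effect += prob * c_eff
            counts = counts + prob * c_counts
        memo[id(n)] = (cost, effect, counts)
        return memo[id(n)]

    cost, effect, counts = value(node)
    return StrategyValue(cost, effect, tuple(counts))


def evaluate_detailed(
    tree: DecisionTree, discount_rate: float = 0.0, discount_effects: bool = False
) -> dict[str, StrategyValue]:
    """Per-strategy expected values via memoized rollback."""
    if discount_rate < 0:
        raise ValueError("discount_rate must be >= 0")
    _require_valid(tree)
    if tree.root.kind == DECISION:
        return {
            child.label: evaluate_node(child, discount_rate, discount_effects)
            for child in tree.root.children
        }
    label = tree.root.label or (tree.strategy_labels[0] if tree.strategy_labels else "")
    return {label: evaluate_node(tree.root, discount_rate, discount_effects)}


def evaluate(
    tree: DecisionTree, discount_rate: float = 0.0, discount_effects: bool = False
) -> dict[str, tuple[float, float]]:
    """Expected (discounted cost, effect) per strategy.

    Rejects invalid trees, naming the first violation.
    """
    detailed = evaluate_detailed(tree, discount_rate, discount_effects)
    return {k: (v.cost, v.effect) for k, v in detailed.items()}


def enumerate_paths(tree: DecisionTree, max_paths: int = 2_000_000) -> list[PathRecord]:
    """Exhaustively list every root-to-leaf path with its probability.

    Intended as a brute-force oracle: on trees with shared subtrees the
    path count grows exponentially with depth, so ``max_paths`` guards
    against accidental blow-up.
    """
    _require_valid(tree)
    paths: list[PathRecord] = []

    def walk(
        n: Node, strategy: str, prob: float, cost: float, effect: float,
        times: tuple[float, ...],
    ) -> None:
        cost += n.payoff.cost
        effect += n.payoff.effect
        times = times + (n.accrual_time,)
        branches = list(_iter_branches(n))
        if not branches:
            if len(paths) >= max_paths:
                raise RuntimeError(f"more than {max_paths} paths; oracle aborted")
            paths.append(PathRecord(strategy, prob, cost, effect, times))
            return
        for p, child in branches:
            if n.kind == DECISION:
                walk(child, child.label, prob, 0.0, 0.0, ())
            else:
                walk(child, strategy, prob * p, cost, effect, times)

    if tree.root.kind == DECISION:
        for child in tree.root.children:
            walk(child, child.label, 1.0, 0.0, 0.0, ())
    else:
        walk(tree.root, tree.root.label, 1.0, 0.0, 0.0, ())
    return paths


def evaluate_by_enumeration(
    tree: DecisionTree, discount_rate: float = 0.0, discount_effects: bool = False
) -> dict[str, tuple[float, float]]:
    """Path-enumeration evaluation: the independent oracle for evaluate().

    Sums probability-weighted discounted payoffs over every enumerated
    path, without any rollback recursion.
    """
    _require_valid(tree)
    out: dict[str, tuple[float, float]] = {}
    roots = tree.root.children if tree.root.kind == DECISION else [tree.root]
    for sub in roots:
        total_cost = 0.0
        total_effect = 0.0
        stack: list[tuple[Node, float]] = [(sub, 1.0)]
        while stack:
            n, prob = stack.pop()
            df = (1.0 + discount_rate) ** (-n.accrual_time)
            total_cost += prob * n.payoff.cost * df
            total_effect += prob * n.payoff.effect * (df if discount_effects else 1.0)
            for p, child in _iter_branches(n):
                stack.append((child, prob * p))
        out[sub.label] = (total_cost, total_effect)
    return out


# ---------------------------------------------------------------------------
# serialization (JSON dialect); shared subtrees are expanded on write

def node_to_dict(node: Node) -> dict:
    d: dict = {
        "kind": node.kind,
        "label": node.label,
        "cost": node.payoff.cost,
        "effect": node.payoff.effect,
        "time": node.accrual_time,
    }
    if node.counts is not None:
        d["counts"] = list(node.counts)
    if node.kind == CHANCE:
        d["children"] = [
            {"probability": p, "node": node_to_dict(c)} for p, c in node.children
        ]
    elif node.kind == DECISION:
        d["children"] = [node_to_dict(c) for c in node.children]
    return d


def node_from_dict(d: dict) -> Node:
    node = Node(
        kind=d["kind"],
        label=d.get("label", ""),
        payoff=Payoff(cost=d.get("cost", 0.0), effect=d.get("effect", 0.0)),
        accrual_time=d.get("time", 0.0),
        counts=tuple(d["counts"]) if "counts" in d else None,
    )
    if node.kind == CHANCE:
        node.children = [
            (c["probability"], node_from_dict(c["node"])) for c in d.get("children", [])
        ]
    elif node.kind == DECISION:
        node.children = [node_from_dict(c) for c in d.get("children", [])]
    return node


def tree_to_json(tree: DecisionTree, indent: int | None = 2) -> str:
    return json.dumps(
        {"strategy_labels": tree.strategy_labels, "root": node_to_dict(tree.root)},
        indent=indent,
    )


def tree_from_json(text: str) -> DecisionTree:
    d = json.loads(text)
    return DecisionTree(
        root=node_from_dict(d["root"]), strategy_labels=list(d["strategy_labels"])
    )


# ---------------------------------------------------------------------------
# randomized small trees for oracle-equivalence testing

def random_tree(
    rng: np.random.Generator,
    n_strategies: int = 2,
    max_depth: int = 4,
    max_branches: int = 3,
    horizon: float = 5.0,
) -> DecisionTree:
    """A random small valid tree for rollback-vs-enumeration checks."""

    def subtree(depth: int) -> Node:
        payoff = Payoff(
            cost=float(rng.uniform(0, 1000)), effect=float(rng.uniform(0, 1))
        )
        t = float(rng.uniform(0, horizon))
        if depth >= max_depth or rng.random() < 0.3:
            return Node(TERMINAL, label=f"t{depth}", payoff=payoff, accrual_time=t)
        k = int(rng.integers(2, max_branches + 1))
        probs = rng.dirichlet(np.ones(k))
        probs = probs / probs.sum()
        children = [(float(p), subtree(depth + 1)) for p in probs]
        return Node(CHANCE, label=f"c{depth}", payoff=payoff, accrual_time=t,
                    children=children)

    root = Node(
        DECISION,
        label="root",
        children=[
            Node(
                CHANCE, label=f"s{i}", children=[(1.0, subtree(1))]
            )
            for i in range(n_strategies)
        ],
    )
    return DecisionTree(root=root, strategy_labels=[f"s{i}" for i in range(n_strategies)])
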