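"""Typed expression trees over tabular features.

A *representation* is an ordered list of expression trees; evaluating it on an
N x d feature matrix yields an N x p matrix of derived features that feed the
logistic layer.  The interpretable operator set is restricted to Boolean
functions: threshold comparisons on raw features (``<``, ``>``), and the
logical connectives AND, OR, NOT.  Comparison thresholds are learned from data
by minimizing weighted Gini impurity, as in classification trees, so that
thresholds stay in the raw (clinical) units of each feature.

An optional continuous operator set (+, -, *, protected /) is provided solely
for ablation experiments that compare the restricted Boolean grammar against
an unrestricted one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .exceptions import ConfigError, DegenerateDataError, StructureError

# node kinds
FEATURE = "feature"
LT = "lt"
GT = "gt"
NOT = "not"
AND = "and"
OR = "or"
ADD = "add"
SUB = "sub"
MUL = "mul"
DIV = "div"
EXP = "exp"
LOG = "log"
SQRT = "sqrt"
SQUARE = "square"
RELU = "relu"
LOGISTIC = "logistic"

BOOLEAN_OPS = frozenset({LT, GT, NOT, AND, OR})
LOGICAL_OPS = frozenset({NOT, AND, OR})
COMPARISON_OPS = frozenset({LT, GT})
ARITHMETIC_OPS = frozenset({ADD, SUB, MUL, DIV, EXP, LOG, SQRT, SQUARE, RELU, LOGISTIC})
ALL_KINDS = frozenset({FEATURE}) | BOOLEAN_OPS | ARITHMETIC_OPS

ARITY = {
    FEATURE: 0,
    LT: 0,
    GT: 0,
    NOT: 1,
    AND: 2,
    OR: 2,
    ADD: 2,
    SUB: 2,
    MUL: 2,
    DIV: 2,
    EXP: 1,
    LOG: 1,
    SQRT: 1,
    SQUARE: 1,
    RELU: 1,
    LOGISTIC: 1,
}

#: Default operator cost table for the complexity metric.  Comparisons and
#: binary connectives cost more than bare feature references so that complexity
#: penalizes logic depth, not only node count.
DEFAULT_OPERATOR_WEIGHTS = {
    FEATURE: 1.0,
    NOT: 1.0,
    LT: 2.0,
    GT: 2.0,
    AND: 2.0,
    OR: 2.0,
    ADD: 2.0,
    SUB: 2.0,
    MUL: 3.0,
    DIV: 4.0,
    SQRT: 2.0,
    SQUARE: 2.0,
    RELU: 2.0,
    LOGISTIC: 3.0,
    EXP: 4.0,
    LOG: 4.0,
}

DEFAULT_OPERATOR_SET = (LT, GT, AND, OR, NOT)
UNRESTRICTED_OPERATOR_SET = DEFAULT_OPERATOR_SET + (
    ADD, SUB, MUL, DIV, EXP, LOG, SQRT, SQUARE, RELU, LOGISTIC,
)


@dataclass(frozen=True)
class Node:
    """One node of an expression tree.

    ``FEATURE`` nodes reference a raw column.  ``LT``/``GT`` nodes are
    leaf-level comparisons: they reference a raw column directly and carry a
    learned threshold, producing a 0/1 column.  Logical nodes combine Boolean
    children; arithmetic nodes combine continuous children.
    """

    kind: str
    feature_index: int | None = None
    threshold: float | None = None
    children: tuple["Node", ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ALL_KINDS:
            raise StructureError(f"unknown node kind {self.kind!r}")
        if len(self.children) != ARITY[self.kind]:
            raise StructureError(
                f"{self.kind} takes {ARITY[self.kind]} children, got {len(self.children)}"
            )
        if self.kind in COMPARISON_OPS or self.kind == FEATURE:
            if self.feature_index is None:
                raise StructureError(f"{self.kind} node requires a feature_index")
        if self.kind in COMPARISON_OPS and self.threshold is None:
            raise StructureError(f"{self.kind} node requires a threshold")

    @property
    def is_boolean(self) -> bool:
        return self.kind in BOOLEAN_OPS

    def walk(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass(frozen=True)
class Representation:
    """An ordered list of expression trees; its evaluation is the derived
    feature matrix fed to the logistic layer."""

    trees: tuple[Node, ...]

    def __post_init__(self) -> None:
        if len(self.trees) < 1:
            raise StructureError("a representation needs at least one tree")

    @property
    def p(self) -> int:
        return len(self.trees)


def feature(index: int) -> Node:
    return Node(FEATURE, feature_index=index)


def lt(index: int, threshold: float) -> Node:
    return Node(LT, feature_index=index, threshold=float(threshold))


def gt(index: int, threshold: float) -> Node:
    return Node(GT, feature_index=index, threshold=float(threshold))


def not_(a: Node) -> Node:
    return Node(NOT, children=(a,))


def and_(a: Node, b: Node) -> Node:
    return Node(AND, children=(a, b))


def or_(a: Node, b: Node) -> Node:
    return Node(OR, children=(a, b))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_node(node: Node, X: np.ndarray) -> np.ndarray:
    if node.kind == FEATURE or node.kind in COMPARISON_OPS:
        if node.feature_index >= X.shape[1] or node.feature_index < 0:
            raise StructureError(
                f"feature index {node.feature_index} out of range for d={X.shape[1]}"
            )
        col = X[:, node.feature_index].astype(float)
        if node.kind == FEATURE:
            return col
        if node.kind == LT:
            return (col < node.threshold).astype(float)
        return (col > node.threshold).astype(float)
    vals = [evaluate_node(c, X) for c in node.children]
    if node.kind == NOT:
        return 1.0 - vals[0]
    if node.kind == AND:
        return np.minimum(vals[0], vals[1])
    if node.kind == OR:
        return np.maximum(vals[0], vals[1])
    if node.kind == ADD:
        return vals[0] + vals[1]
    if node.kind == SUB:
        return vals[0] - vals[1]
    if node.kind == MUL:
        return vals[0] * vals[1]
    if node.kind == DIV:  # protected division
        denom = vals[1]
        return np.where(
            np.abs(denom) > 1e-12, vals[0] / np.where(denom == 0, 1.0, denom), 1.0
        )
    if node.kind == EXP:
        return np.exp(np.clip(vals[0], -20.0, 20.0))
    if node.kind == LOG:  # protected log
        return np.log(np.abs(vals[0]) + 1e-12)
    if node.kind == SQRT:
        return np.sqrt(np.abs(vals[0]))
    if node.kind == SQUARE:
        return vals[0] ** 2
    if node.kind == RELU:
        return np.maximum(vals[0], 0.0)
    # logistic squash
    z = np.clip(vals[0], -30.0, 30.0)
    return 1.0 / (1.0 + np.exp(-z))


def evaluate(rep: Representation, X: np.ndarray) -> np.ndarray:
    """Evaluate a representation into an N x p derived-feature matrix."""
    X = np.asarray(X, dtype=float)
    cols = [evaluate_node(t, X) for t in rep.trees]
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# metrics on trees
# ---------------------------------------------------------------------------

def node_size(node: Node) -> int:
    if node.kind == FEATURE:
        return 1
    if node.kind in COMPARISON_OPS:
        return 2  # one split node plus one feature leaf
    return 1 + sum(node_size(c) for c in node.children)


def size(rep: Representation) -> int:
    """Total number of split, operator, and feature-leaf nodes across trees."""
    return sum(node_size(t) for t in rep.trees)


def node_depth(node: Node) -> int:
    if node.kind == FEATURE:
        return 0
    if node.kind in COMPARISON_OPS:
        return 1
    return 1 + max(node_depth(c) for c in node.children)


def node_complexity(node: Node, weights: dict[str, float]) -> float:
    try:
        w = weights[node.kind]
    except KeyError as exc:
        raise ConfigError(f"no complexity weight for operator {node.kind!r}") from exc
    if node.kind == FEATURE:
        return w
    if node.kind in COMPARISON_OPS:
        # a comparison is an operator applied to an implicit feature leaf
        return w * (1.0 + weights.get(FEATURE, 1.0))
    return w * (1.0 + sum(node_complexity(c, weights) for c in node.children))


def complexity(rep: Representation, weights: dict[str, float] | None = None) -> float:
    """Recursive weighted operator cost; with all weights 1 this is a node count."""
    if weights is None:
        weights = DEFAULT_OPERATOR_WEIGHTS
    for k, w in weights.items():
        if w <= 0:
            raise ConfigError(f"operator weight for {k!r} must be positive")
    return sum(node_complexity(t, weights) for t in rep.trees)


# ---------------------------------------------------------------------------
# Gini threshold learning
# ---------------------------------------------------------------------------

def threshold_candidates(column: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive sorted distinct values of the column."""
    vals = np.unique(np.asarray(column, dtype=float))
    if vals.size < 2:
        raise DegenerateDataError("constant column has no candidate thresholds")
    return (vals[:-1] + vals[1:]) / 2.0


def learn_threshold(
    column: np.ndarray,
    labels: np.ndarray,
    sample_weight: np.ndarray | None = None,
) -> float:
    """Weighted-Gini-optimal split threshold for ``column > theta``.

    The candidate grid is the midpoints between consecutive distinct values, so
    the returned threshold always lies strictly between two observed values.
    Ties in impurity are broken toward the smallest threshold.
    """
    column = np.asarray(column, dtype=float)
    labels = np.asarray(labels)
    if sample_weight is None:
        sample_weight = np.ones_like(column)
    sample_weight = np.asarray(sample_weight, dtype=float)
    if column.size < 2:
        raise DegenerateDataError("need at least two samples to learn a threshold")

    order = np.argsort(column, kind="stable")
    col = column[order]
    w = sample_weight[order]
    w1 = w * (labels[order] == 1)
    w0 = w - w1

    # boundaries between distinct consecutive values
    change = np.nonzero(np.diff(col) > 0)[0]  # left group = col[: i + 1]
    if change.size == 0:
        raise DegenerateDataError("constant column has no candidate thresholds")

    cw = np.cumsum(w)
    cw1 = np.cumsum(w1)
    cw0 = np.cumsum(w0)
    W, W1, W0 = cw[-1], cw1[-1], cw0[-1]

    wl = cw[change]
    wl1 = cw1[change]
    wl0 = cw0[change]
    wr = W - wl
    wr1 = W1 - wl1
    wr0 = W0 - wl0

    with np.errstate(divide="ignore", invalid="ignore"):
        gini_l = 1.0 - (wl1 / wl) ** 2 - (wl0 / wl) ** 2
        gini_r = 1.0 - (wr1 / wr) ** 2 - (wr0 / wr) ** 2
    gini_l = np.nan_to_num(gini_l)
    gini_r = np.nan_to_num(gini_r)
    impurity = (wl * gini_l + wr * gini_r) / W

    best = int(np.argmin(impurity))  # argmin takes the first (smallest theta) on ties
    return float((col[change[best]] + col[change[best] + 1]) / 2.0)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _check_node(node: Node, d: int, violations: list[str], path: str) -> None:
    if node.kind in COMPARISON_OPS or node.kind == FEATURE:
        if not (0 <= node.feature_index < d):
            violations.append(
                f"{path}: feature index {node.feature_index} out of range [0, {d})"
            )
    if node.kind in LOGICAL_OPS:
        for i, c in enumerate(node.children):
            if not c.is_boolean:
                violations.append(f"{path}.{i}: {node.kind} child must be Boolean, got {c.kind}")
    if node.kind in ARITHMETIC_OPS:
        for i, c in enumerate(node.children):
            if c.is_boolean:
                violations.append(
                    f"{path}.{i}: {node.kind} child must be continuous, got {c.kind}"
                )
    for i, c in enumerate(node.children):
        _check_node(c, d, violations, f"{path}.{i}")


def validate(
    rep: Representation,
    d: int,
    max_dim: int,
    max_depth: int,
    operator_set: Sequence[str] | None = None,
) -> list[str]:
    """Return a list of invariant violations (empty when the representation is valid)."""
    violations: list[str] = []
    if not (1 <= rep.p <= max_dim):
        violations.append(f"dimensionality {rep.p} outside [1, {max_dim}]")
    allowed = set(operator_set) | {FEATURE} if operator_set is not None else None
    for t, tree in enumerate(rep.trees):
        _check_node(tree, d, violations, f"tree{t}")
        if node_depth(tree) > max_depth:
            violations.append(f"tree{t}: depth {node_depth(tree)} exceeds {max_depth}")
        if allowed is not None:
            for n in tree.walk():
                if n.kind not in allowed:
                    violations.append(f"tree{t}: operator {n.kind} not in operator set")
    return violations


# ---------------------------------------------------------------------------
# serialization & display
# ---------------------------------------------------------------------------

def node_to_dict(node: Node, feature_names: Sequence[str] | None = None) -> dict:
    d: dict = {"kind": node.kind}
    if node.feature_index is not None:
        d["feature_index"] = node.feature_index
        if feature_names is not None:
            d["feature_name"] = feature_names[node.feature_index]
    if node.threshold is not None:
        d["threshold"] = node.threshold
    if node.children:
        d["children"] = [node_to_dict(c, feature_names) for c in node.children]
    return d


def node_from_dict(d: dict) -> Node:
    return Node(
        kind=d["kind"],
        feature_index=d.get("feature_index"),
        threshold=d.get("threshold"),
        children=tuple(node_from_dict(c) for c in d.get("children", ())),
    )


def rep_to_dict(rep: Representation, feature_names: Sequence[str] | None = None) -> dict:
    return {"trees": [node_to_dict(t, feature_names) for t in rep.trees]}


def rep_from_dict(d: dict) -> Representation:
    return Representation(trees=tuple(node_from_dict(t) for t in d["trees"]))


def describe_node(node: Node, feature_names: Sequence[str] | None = None) -> str:
    """Human-readable one-line rendering, e.g. ``(# enc 3+ meds, sum > 1)``."""

    def name(i: int) -> str:
        return feature_names[i] if feature_names is not None else f"x{i}"

    if node.kind == FEATURE:
        return name(node.feature_index)
    if node.kind == LT:
        return f"{name(node.feature_index)} < {node.threshold:g}"
    if node.kind == GT:
        return f"{name(node.feature_index)} > {node.threshold:g}"
    if node.kind == NOT:
        return f"NOT ({describe_node(node.children[0], feature_names)})"
    if ARITY[node.kind] == 1:
        return f"{node.kind}({describe_node(node.children[0], feature_names)})"
    sym = {AND: "AND", OR: "OR", ADD: "+", SUB: "-", MUL: "*", DIV: "/"}[node.kind]
    a, b = (describe_node(c, feature_names) for c in node.children)
    return f"({a} {sym} {b})"
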