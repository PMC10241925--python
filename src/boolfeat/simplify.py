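"""Bloat control: correlation pruning and post-run model simplification.

Evolved representations tend to carry redundant structure (duplicated
subtrees, double negations, highly correlated derived features).  Two
mechanisms combat this:

* :func:`prune_correlated` — drop one member of the most-correlated pair of
  derived features, keeping the one more correlated with the outcome.
* :func:`simplify_post_run` — a three-phase hill climb applied to final
  models: (1) exact logical rewrites, (2) iterated correlation deletions,
  (3) iterated uniform subtree deletions; non-exact changes are accepted only
  while the cumulative mean absolute change in predicted probability against
  the original model stays within a tolerance, refitting the logistic layer
  after every accepted change.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import expressions as ex
from .expressions import AND, FEATURE, NOT, OR, Node, Representation
from .logistic import Model, class_weights, fit_model


# ---------------------------------------------------------------------------
# correlation pruning
# ---------------------------------------------------------------------------

def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def correlated_pair(Phi: np.ndarray, y: np.ndarray) -> tuple[int, float]:
    """Index to delete under the correlation-pruning rule, and the pair's |r|.

    Scans all column pairs for the maximal absolute Pearson correlation
    (ties: first pair in scan order); within that pair the member with the
    smaller absolute correlation with the outcome is deleted (tie: the later
    column).
    """
    p = Phi.shape[1]
    best_pair, best_r = (0, 1), -1.0
    for i in range(p):
        for j in range(i + 1, p):
            r = abs(_safe_corr(Phi[:, i], Phi[:, j]))
            if r > best_r:
                best_r, best_pair = r, (i, j)
    i, j = best_pair
    ry_i = abs(_safe_corr(Phi[:, i], y.astype(float)))
    ry_j = abs(_safe_corr(Phi[:, j], y.astype(float)))
    delete = j if ry_j <= ry_i else i
    return delete, best_r


def prune_correlated(
    rep: Representation, X: np.ndarray, y: np.ndarray
) -> Representation:
    """Delete the more redundant member of the most-correlated feature pair."""
    if rep.p < 2:
        warnings.warn("prune_correlated is a no-op on a 1-dimensional representation",
                      stacklevel=2)
        return rep
    Phi = ex.evaluate(rep, X)
    delete, _ = correlated_pair(Phi, y)
    trees = tuple(t for k, t in enumerate(rep.trees) if k != delete)
    return Representation(trees=trees)


# ---------------------------------------------------------------------------
# exact logical rewrites
# ---------------------------------------------------------------------------

def _flatten(kind: str, node: Node) -> list[Node]:
    if node.kind == kind:
        return _flatten(kind, node.children[0]) + _flatten(kind, node.children[1])
    return [node]


def _rebuild_chain(kind: str, operands: list[Node]) -> Node:
    out = operands[0]
    for nxt in operands[1:]:
        out = Node(kind, children=(out, nxt))
    return out


def _rewrite(node: Node) -> Node:
    children = tuple(_rewrite(c) for c in node.children)
    node = Node(node.kind, node.feature_index, node.threshold, children)
    if node.kind == NOT and children[0].kind == NOT:
        return children[0].children[0]
    if node.kind in (AND, OR):
        # collapse duplicate operands across the whole associative chain
        operands: list[Node] = []
        for op in _flatten(node.kind, node):
            if op not in operands:
                operands.append(op)
        return _rebuild_chain(node.kind, operands)
    return node


def remove_redundant_ops(rep: Representation) -> Representation:
    """Rewrite each tree to a fixpoint of exact, prediction-preserving rules.

    NOT(NOT(a)) -> a; AND(a, a) -> a; OR(a, a) -> a; duplicated operands in
    nested serial AND/OR chains are collapsed.
    """
    trees = []
    for tree in rep.trees:
        cur = tree
        for _ in range(100):  # fixpoint; bounded for safety
            nxt = _rewrite(cur)
            if nxt == cur:
                break
            cur = nxt
        trees.append(cur)
    return Representation(trees=tuple(trees))


# ---------------------------------------------------------------------------
# post-run simplification
# ---------------------------------------------------------------------------

def _subtree_positions(rep: Representation) -> list[tuple[int, tuple[int, ...]]]:
    """All (tree index, path) positions; path () is the tree root."""
    out = []

    def rec(node: Node, t: int, path: tuple[int, ...]) -> None:
        out.append((t, path))
        for i, c in enumerate(node.children):
            rec(c, t, path + (i,))

    for t, tree in enumerate(rep.trees):
        rec(tree, t, ())
    return out


def _node_at(node: Node, path: tuple[int, ...]) -> Node:
    for i in path:
        node = node.children[i]
    return node


def _replace_at(node: Node, path: tuple[int, ...], new: Node) -> Node:
    if not path:
        return new
    children = list(node.children)
    children[path[0]] = _replace_at(children[path[0]], path[1:], new)
    return Node(node.kind, node.feature_index, node.threshold, tuple(children))


def _shrink_proposal(
    rep: Representation, rng: np.random.Generator
) -> Representation | None:
    """Uniform subtree deletion: replace a random subtree by a type-correct leaf.

    Roots of multi-tree representations may be deleted outright; an internal
    operator node is replaced by one of its children (NOT: its child; AND/OR
    and arithmetic: a random child), which preserves output type.
    """
    positions = _subtree_positions(rep)
    t, path = positions[rng.integers(len(positions))]
    node = _node_at(rep.trees[t], path)
    if not path:
        if rep.p > 1:
            return Representation(tuple(tr for k, tr in enumerate(rep.trees) if k != t))
        if node.children:
            # shrink the single root toward a child of the same output type
            cands = [c for c in node.children if c.is_boolean == node.is_boolean]
            if cands:
                child = cands[rng.integers(len(cands))]
                return Representation((child,) + rep.trees[1:])
        return None
    if not node.children:
        return None
    cands = [c for c in node.children if c.is_boolean == node.is_boolean]
    if not cands:
        return None
    child = cands[rng.integers(len(cands))]
    new_tree = _replace_at(rep.trees[t], path, child)
    trees = list(rep.trees)
    trees[t] = new_tree
    return Representation(tuple(trees))


def simplify_post_run(
    model: Model,
    X: np.ndarray,
    y: np.ndarray,
    tolerance: float = 0.005,
    rng: np.random.Generator | None = None,
    ridge: float = 1e-6,
    operator_weights: dict[str, float] | None = None,
) -> Model:
    """Three-phase hill-climbing simplification of a fitted model.

    ``tolerance`` bounds the cumulative mean absolute change in predicted
    probability on the training data relative to the *original* model; phase-1
    rewrites and deletions of perfectly correlated pairs are treated as exact
    and accepted unconditionally.  Never increases size or complexity.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    w = class_weights(y)
    p0 = model.predict_proba(X)
    names = model.feature_names

    def refit(rep: Representation) -> Model:
        m, _ = fit_model(rep, X, y, w, ridge=ridge,
                         operator_weights=operator_weights, feature_names=names)
        m.decision_threshold = model.decision_threshold
        m.training_meta = dict(model.training_meta)
        return m

    def drift(m: Model) -> float:
        return float(np.mean(np.abs(m.predict_proba(X) - p0)))

    # Phase 1: exact rewrites (feature columns unchanged, so the refit is exact)
    rep = remove_redundant_ops(model.representation)
    current = refit(rep) if rep != model.representation else model

    # Phase 2: iterated correlation deletion
    while current.representation.p >= 2:
        Phi = ex.evaluate(current.representation, X)
        delete, r = correlated_pair(Phi, y)
        trees = tuple(
            t for k, t in enumerate(current.representation.trees) if k != delete
        )
        candidate = refit(Representation(trees))
        if r >= 1.0 - 1e-12 or drift(candidate) <= tolerance:
            current = candidate
        else:
            break

    # Phase 3: iterated uniform subtree deletion under the same cumulative rule
    budget = 5 * max(1, ex.size(current.representation))
    misses = 0
    while budget > 0 and misses < 2 * max(1, ex.size(current.representation)):
        budget -= 1
        proposal = _shrink_proposal(current.representation, rng)
        if proposal is None or proposal == current.representation:
            misses += 1
            continue
        candidate = refit(proposal)
        if drift(candidate) <= tolerance:
            current = candidate
            misses = 0
        else:
            misses += 1

    return current
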