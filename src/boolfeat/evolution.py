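"""Population-based search over feature representations.

Each generation: parents are chosen by epsilon-lexicase selection on the
per-subject balanced losses (which preserves candidates that do well on rare
or difficult subjects), offspring are produced by tree variation operators,
every candidate's logistic layer is refit on the internal training split, and
survival is decided by an NSGA-II step on the two objectives (training
balanced log-loss, representation complexity).  All non-dominated candidates
ever evaluated accumulate in a Pareto archive; after the loop the archive is
post-run simplified and the final model is the archive member with the lowest
balanced loss on the internal validation split.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import expressions as ex
from .datasets import Dataset, split_train_validation
from .exceptions import ConfigError, DegenerateDataError
from .logistic import FitnessRecord, Model, class_weights, fit_logistic, fit_model
from .selection import select_final
from .simplify import (
    _node_at,
    _replace_at,
    _shrink_proposal,
    _subtree_positions,
    prune_correlated,
    simplify_post_run,
)

DEFAULT_VARIATION_RATES = {
    "insertion": 0.2,
    "deletion": 0.2,
    "point": 0.3,
    "crossover": 0.2,
    "correlation_deletion": 0.1,
}


@dataclass
class EvolutionConfig:
    pop_size: int = 100
    generations: int = 100
    max_dim: int = 10
    max_depth: int = 3
    operator_set: tuple[str, ...] = ex.DEFAULT_OPERATOR_SET
    variation_rates: dict = field(default_factory=lambda: dict(DEFAULT_VARIATION_RATES))
    epsilon_mode: str = "mad"
    seed: int = 0
    simplify_tolerance: float = 0.005
    post_run_simplify: bool = True
    validation_frac: float = 0.20
    ridge: float = 1e-6
    #: legacy-style initialization: weight features by their coefficients in a
    #: joint multivariate logistic model and seed the population with that
    #: full linear model (capped at max_dim features by |coefficient|)
    init_full_linear: bool = False
    operator_weights: dict = field(
        default_factory=lambda: dict(ex.DEFAULT_OPERATOR_WEIGHTS)
    )

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ConfigError("pop_size must be at least 4")
        if self.max_dim < 1:
            raise ConfigError("max_dim must be at least 1")
        rates = self.variation_rates
        if any(r < 0 for r in rates.values()):
            raise ConfigError("variation rates must be nonnegative")
        if abs(sum(rates.values()) - 1.0) > 1e-9:
            raise ConfigError("variation rates must sum to 1")
        if self.epsilon_mode not in ("mad", "zero"):
            raise ConfigError("epsilon_mode must be 'mad' or 'zero'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["operator_set"] = list(self.operator_set)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _dominates(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] <= b[0] and a[1] <= b[1] and (a[0] < b[0] or a[1] < b[1])


@dataclass
class ParetoArchive:
    """Cumulative set of mutually non-dominated (loss, complexity) candidates."""

    members: list[tuple[Model, FitnessRecord]] = field(default_factory=list)

    def update(self, model: Model, record: FitnessRecord) -> bool:
        obj = (record.balanced_loss, record.complexity)
        for _, r in self.members:
            o = (r.balanced_loss, r.complexity)
            if _dominates(o, obj) or o == obj:
                return False
        self.members = [
            (m, r)
            for m, r in self.members
            if not _dominates(obj, (r.balanced_loss, r.complexity))
        ]
        self.members.append((model, record))
        return True

    def __len__(self) -> int:
        return len(self.members)

    @property
    def models(self) -> list[Model]:
        return [m for m, _ in self.members]


# ---------------------------------------------------------------------------
# initial feature weighting
# ---------------------------------------------------------------------------

def univariate_feature_weights(ds: Dataset, ridge: float = 1e-6) -> np.ndarray:
    """Normalized |coefficient| of each standardized feature in a univariate
    balanced logistic regression; used to bias feature sampling."""
    w = class_weights(ds.y)
    out = np.empty(ds.d)
    for j in range(ds.d):
        col = ds.X[:, j]
        sd = col.std()
        if sd == 0:
            raise DegenerateDataError(
                f"zero-variance feature {ds.feature_names[j]!r} reached weighting; "
                "run preprocess first"
            )
        z = (col - col.mean()) / sd
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta, _ = fit_logistic(z[:, None], ds.y, w, ridge=ridge)
        out[j] = abs(beta[0])
    total = out.sum()
    if total == 0:
        return np.full(ds.d, 1.0 / ds.d)
    return out / total


# ---------------------------------------------------------------------------
# search context: caches tied to one training split
# ---------------------------------------------------------------------------

def multivariate_feature_weights(ds: Dataset, ridge: float = 1e-3) -> np.ndarray:
    """Normalized |coefficient| of each standardized feature in one joint
    balanced logistic regression (legacy initial weighting)."""
    w = class_weights(ds.y)
    sd = ds.X.std(axis=0)
    if np.any(sd == 0):
        raise DegenerateDataError("zero-variance feature reached weighting")
    Z = (ds.X - ds.X.mean(axis=0)) / sd
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta, _ = fit_logistic(Z, ds.y, w, ridge=ridge)
    out = np.abs(beta)
    return out / out.sum() if out.sum() > 0 else np.full(ds.d, 1.0 / ds.d)


class _SearchContext:
    def __init__(self, train: Dataset, cfg: EvolutionConfig):
        self.train = train
        self.cfg = cfg
        self.class_w = class_weights(train.y)
        if cfg.init_full_linear:
            self.feature_weights = multivariate_feature_weights(train, max(cfg.ridge, 1e-3))
        else:
            self.feature_weights = univariate_feature_weights(train, cfg.ridge)
        # features usable in comparisons: need >= 2 distinct values
        self.splittable = np.array(
            [np.unique(train.X[:, j]).size >= 2 for j in range(train.d)]
        )
        if not self.splittable.any():
            raise DegenerateDataError("no feature has two distinct values")
        sw = self.feature_weights * self.splittable
        self.split_weights = sw / sw.sum() if sw.sum() > 0 else (
            self.splittable / self.splittable.sum()
        )
        self._theta: dict[int, float] = {}
        self._grid: dict[int, np.ndarray] = {}
        self._eval_cache: dict[ex.Representation, tuple[Model, FitnessRecord]] = {}

    def gini_threshold(self, j: int) -> float:
        if j not in self._theta:
            self._theta[j] = ex.learn_threshold(
                self.train.X[:, j], self.train.y, self.class_w
            )
        return self._theta[j]

    def threshold_grid(self, j: int) -> np.ndarray:
        if j not in self._grid:
            self._grid[j] = ex.threshold_candidates(self.train.X[:, j])
        return self._grid[j]

    def sample_feature(self, rng: np.random.Generator, splittable_only: bool) -> int:
        p = self.split_weights if splittable_only else self.feature_weights
        return int(rng.choice(self.train.d, p=p))

    def random_comparison(self, rng: np.random.Generator) -> ex.Node:
        j = self.sample_feature(rng, splittable_only=True)
        kind = ex.LT if rng.random() < 0.5 else ex.GT
        return ex.Node(kind, feature_index=j, threshold=self.gini_threshold(j))

    def random_boolean_tree(self, rng: np.random.Generator, depth: int) -> ex.Node:
        logical = [k for k in self.cfg.operator_set if k in ex.LOGICAL_OPS]
        if depth <= 1 or not logical or rng.random() < 0.3:
            return self.random_comparison(rng)
        kind = logical[rng.integers(len(logical))]
        if kind == ex.NOT:
            return ex.Node(ex.NOT, children=(self.random_boolean_tree(rng, depth - 1),))
        return ex.Node(
            kind,
            children=(
                self.random_boolean_tree(rng, depth - 1),
                self.random_boolean_tree(rng, depth - 1),
            ),
        )

    def random_continuous_tree(self, rng: np.random.Generator, depth: int) -> ex.Node:
        arith = [k for k in self.cfg.operator_set if k in ex.ARITHMETIC_OPS]
        if depth <= 0 or not arith or rng.random() < 0.4:
            return ex.feature(self.sample_feature(rng, splittable_only=False))
        kind = arith[rng.integers(len(arith))]
        children = tuple(
            self.random_continuous_tree(rng, depth - 1)
            for _ in range(ex.ARITY[kind])
        )
        return ex.Node(kind, children=children)

    def random_tree(self, rng: np.random.Generator) -> ex.Node:
        depth = int(rng.integers(1, self.cfg.max_depth + 1))
        has_arith = any(k in ex.ARITHMETIC_OPS for k in self.cfg.operator_set)
        if has_arith and rng.random() < 0.5:
            return self.random_continuous_tree(rng, depth)
        return self.random_boolean_tree(rng, depth)

    def evaluate_candidate(
        self, rep: ex.Representation
    ) -> tuple[Model, FitnessRecord]:
        cached = self._eval_cache.get(rep)
        if cached is not None:
            return cached
        out = fit_model(
            rep,
            self.train.X,
            self.train.y,
            self.class_w,
            ridge=self.cfg.ridge,
            operator_weights=self.cfg.operator_weights,
            feature_names=self.train.feature_names,
        )
        self._eval_cache[rep] = out
        return out


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def init_population(
    ds: Dataset, cfg: EvolutionConfig, rng: np.random.Generator,
    ctx: _SearchContext | None = None,
) -> list[ex.Representation]:
    """Half linear seeds (bare features sampled by univariate weight), half
    random typed trees with Gini-learned comparison thresholds."""
    if ctx is None:
        ctx = _SearchContext(ds, cfg)
    pop: list[ex.Representation] = []
    n_linear = cfg.pop_size // 2
    max_k = min(cfg.max_dim, ds.d)
    if cfg.init_full_linear:
        # seed with the joint linear model over the top-|coefficient| features
        top = np.argsort(-ctx.feature_weights, kind="stable")[:max_k]
        pop.append(ex.Representation(tuple(ex.feature(int(j)) for j in np.sort(top))))
    for _ in range(n_linear):
        k = int(rng.integers(1, max_k + 1))
        idx = rng.choice(ds.d, size=k, replace=False, p=ctx.feature_weights)
        pop.append(ex.Representation(tuple(ex.feature(int(j)) for j in idx)))
    while len(pop) < cfg.pop_size:
        p = int(rng.integers(1, cfg.max_dim + 1))
        trees = tuple(ctx.random_tree(rng) for _ in range(p))
        pop.append(ex.Representation(trees))
    return pop


# ---------------------------------------------------------------------------
# epsilon-lexicase selection
# ---------------------------------------------------------------------------

def epsilon_lexicase_select(
    loss_matrix: np.ndarray,
    n_parents: int,
    rng: np.random.Generator,
    epsilon_mode: str = "mad",
) -> np.ndarray:
    """Select parent indices by filtering candidates case-by-case in random
    order, keeping those within epsilon of the per-case elite.

    Epsilon is the median absolute deviation of the case's losses over the
    surviving pool (``mad``) or zero (``zero``).
    """
    L = np.asarray(loss_matrix, dtype=float)
    if L.ndim != 2 or L.shape[0] == 0:
        raise ValueError("loss matrix must be a nonempty 2-D array")
    n_cand, n_cases = L.shape
    # group candidates with identical loss vectors: no case can separate them
    groups = np.unique(np.round(L, 12), axis=0, return_inverse=True)[1]
    parents = np.empty(n_parents, dtype=int)
    for k in range(n_parents):
        surv = np.arange(n_cand)
        if not np.all(groups == groups[0]):
            for c in rng.permutation(n_cases):
                col = L[surv, c]
                elite = col.min()
                if epsilon_mode == "mad":
                    eps = float(np.median(np.abs(col - np.median(col))))
                else:
                    eps = 0.0
                surv = surv[col <= elite + eps]
                if np.all(groups[surv] == groups[surv[0]]):
                    break
        parents[k] = surv[rng.integers(surv.size)]
    return parents


# ---------------------------------------------------------------------------
# variation
# ---------------------------------------------------------------------------

def _point_mutation(
    rep: ex.Representation, ctx: _SearchContext, rng: np.random.Generator
) -> ex.Representation:
    positions = _subtree_positions(rep)
    t, path = positions[rng.integers(len(positions))]
    node = _node_at(rep.trees[t], path)
    new: ex.Node | None = None
    if node.kind in (ex.AND, ex.OR):
        new = ex.Node(ex.OR if node.kind == ex.AND else ex.AND, children=node.children)
    elif node.kind in (ex.LT, ex.GT):
        choice = rng.integers(3)
        if choice == 0:  # toggle direction, threshold re-learned
            kind = ex.GT if node.kind == ex.LT else ex.LT
            new = ex.Node(kind, node.feature_index,
                          ctx.gini_threshold(node.feature_index))
        elif choice == 1:  # resample the feature
            j = ctx.sample_feature(rng, splittable_only=True)
            new = ex.Node(node.kind, j, ctx.gini_threshold(j))
        else:  # perturb threshold to an adjacent candidate midpoint
            grid = ctx.threshold_grid(node.feature_index)
            i = int(np.searchsorted(grid, node.threshold))
            i = min(max(i + (1 if rng.random() < 0.5 else -1), 0), grid.size - 1)
            new = ex.Node(node.kind, node.feature_index, float(grid[i]))
    elif node.kind == ex.FEATURE:
        new = ex.feature(ctx.sample_feature(rng, splittable_only=False))
    if new is None or new == node:
        return rep
    trees = list(rep.trees)
    trees[t] = _replace_at(rep.trees[t], path, new)
    return ex.Representation(tuple(trees))


def _insertion(
    rep: ex.Representation, ctx: _SearchContext, rng: np.random.Generator
) -> ex.Representation:
    cfg = ctx.cfg
    if rep.p < cfg.max_dim:
        return ex.Representation(rep.trees + (ctx.random_tree(rng),))
    boolean_roots = [i for i, tr in enumerate(rep.trees) if tr.is_boolean]
    if not boolean_roots:
        return rep
    i = boolean_roots[rng.integers(len(boolean_roots))]
    root = rep.trees[i]
    if rng.random() < 1 / 3:
        wrapped = ex.not_(root)
    else:
        kind = ex.AND if rng.random() < 0.5 else ex.OR
        wrapped = ex.Node(kind, children=(root, ctx.random_comparison(rng)))
    if ex.node_depth(wrapped) > cfg.max_depth:
        return rep
    trees = list(rep.trees)
    trees[i] = wrapped
    return ex.Representation(tuple(trees))


def _deletion(
    rep: ex.Representation, ctx: _SearchContext, rng: np.random.Generator
) -> ex.Representation:
    if rep.p > 1:
        i = int(rng.integers(rep.p))
        return ex.Representation(tuple(t for k, t in enumerate(rep.trees) if k != i))
    out = _shrink_proposal(rep, rng)
    return out if out is not None else rep


def _crossover(
    rep: ex.Representation,
    donor: ex.Representation,
    cfg: EvolutionConfig,
    rng: np.random.Generator,
) -> ex.Representation:
    if rng.random() < 0.5:  # exchange one whole tree
        i = int(rng.integers(rep.p))
        j = int(rng.integers(donor.p))
        trees = list(rep.trees)
        trees[i] = donor.trees[j]
        return ex.Representation(tuple(trees))
    # type-compatible subtree exchange
    rec_pos = _subtree_positions(rep)
    t, path = rec_pos[rng.integers(len(rec_pos))]
    target = _node_at(rep.trees[t], path)
    donor_pos = [
        (dt, dp)
        for dt, dp in _subtree_positions(donor)
        if _node_at(donor.trees[dt], dp).is_boolean == target.is_boolean
    ]
    if not donor_pos:
        return rep
    dt, dp = donor_pos[rng.integers(len(donor_pos))]
    graft = _node_at(donor.trees[dt], dp)
    trees = list(rep.trees)
    trees[t] = _replace_at(rep.trees[t], path, graft)
    out = ex.Representation(tuple(trees))
    if any(ex.node_depth(tr) > cfg.max_depth for tr in out.trees):
        return rep
    return out


def vary(
    parents: list[ex.Representation],
    ctx: _SearchContext,
    rng: np.random.Generator,
    diagnostics: dict | None = None,
) -> list[ex.Representation]:
    """One offspring per parent, each produced by exactly one variation
    operation; offspring failing validation fall back to a parent copy."""
    cfg = ctx.cfg
    ops = list(cfg.variation_rates)
    probs = np.array([cfg.variation_rates[o] for o in ops])
    offspring = []
    for parent in parents:
        op = ops[int(rng.choice(len(ops), p=probs))]
        if op == "insertion":
            child = _insertion(parent, ctx, rng)
        elif op == "deletion":
            child = _deletion(parent, ctx, rng)
        elif op == "point":
            child = _point_mutation(parent, ctx, rng)
        elif op == "crossover":
            donor = parents[int(rng.integers(len(parents)))]
            child = _crossover(parent, donor, cfg, rng)
        else:  # correlation_deletion
            if parent.p >= 2:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    child = prune_correlated(parent, ctx.train.X, ctx.train.y)
            else:
                child = parent
        if ex.validate(child, ctx.train.d, cfg.max_dim, cfg.max_depth):
            child = parent  # invalid offspring: keep a copy of the parent
            if diagnostics is not None:
                diagnostics["fallback_copies"] = diagnostics.get("fallback_copies", 0) + 1
        if diagnostics is not None and child == parent:
            diagnostics["unchanged"] = diagnostics.get("unchanged", 0) + 1
        offspring.append(child)
    return offspring


# ---------------------------------------------------------------------------
# NSGA-II survival
# ---------------------------------------------------------------------------

def fast_non_dominated_sort(objectives: np.ndarray) -> list[np.ndarray]:
    """Peel Pareto fronts; front 0 is the non-dominated set."""
    obj = np.asarray(objectives, dtype=float)
    f0, f1 = obj[:, 0], obj[:, 1]
    le = (f0[:, None] <= f0[None, :]) & (f1[:, None] <= f1[None, :])
    strict = (f0[:, None] < f0[None, :]) | (f1[:, None] < f1[None, :])
    dom = le & strict  # dom[i, j]: i dominates j
    n_dominators = dom.sum(axis=0)
    fronts: list[np.ndarray] = []
    assigned = np.zeros(len(obj), dtype=bool)
    while not assigned.all():
        front = np.nonzero((n_dominators == 0) & ~assigned)[0]
        fronts.append(front)
        assigned[front] = True
        n_dominators = n_dominators - dom[front].sum(axis=0)
    return fronts


def crowding_distance(objectives: np.ndarray) -> np.ndarray:
    obj = np.asarray(objectives, dtype=float)
    n = len(obj)
    dist = np.zeros(n)
    for m in range(obj.shape[1]):
        order = np.argsort(obj[:, m], kind="stable")
        vals = obj[order, m]
        dist[order[0]] = dist[order[-1]] = np.inf
        span = vals[-1] - vals[0]
        if span > 0 and n > 2:
            dist[order[1:-1]] += (vals[2:] - vals[:-2]) / span
    return dist


def nsga2_survive(
    objectives: np.ndarray, pop_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of survivors: fill front-by-front; the last, partially taken
    front is ordered by descending crowding distance (random tie-breaks)."""
    fronts = fast_non_dominated_sort(objectives)
    survivors: list[int] = []
    for front in fronts:
        if len(survivors) + len(front) <= pop_size:
            survivors.extend(front.tolist())
            continue
        crowd = crowding_distance(np.asarray(objectives)[front])
        order = np.lexsort((rng.random(len(front)), -crowd))
        need = pop_size - len(survivors)
        survivors.extend(front[order[:need]].tolist())
        break
    return np.array(survivors, dtype=int)


# ---------------------------------------------------------------------------
# top-level run loop
# ---------------------------------------------------------------------------

def run(
    ds: Dataset, cfg: EvolutionConfig
) -> tuple[ParetoArchive, Model, list[dict]]:
    """Full search on a preprocessed dataset.

    Internally splits off a validation fraction, evolves representations on
    the training part, accumulates the Pareto archive, simplifies the archive
    post-run, and selects the final model by validation balanced log-loss.
    Deterministic for a fixed config (including seed).
    """
    rng = np.random.default_rng(cfg.seed)
    train, val = split_train_validation(ds, cfg.validation_frac, cfg.seed)
    ctx = _SearchContext(train, cfg)
    history: list[dict] = []
    archive = ParetoArchive()

    pop = init_population(train, cfg, rng, ctx)
    evals = [ctx.evaluate_candidate(r) for r in pop]
    for model, record in evals:
        archive.update(model, record)

    def log_generation(gen: int) -> None:
        losses = [r.balanced_loss for _, r in evals]
        cxs = [r.complexity for _, r in evals]
        history.append(
            {
                "generation": gen,
                "best_loss": float(min(losses)),
                "median_complexity": float(np.median(cxs)),
                "archive_size": len(archive),
            }
        )

    log_generation(0)
    diagnostics: dict = {}
    for gen in range(1, cfg.generations + 1):
        L = np.stack([r.per_case_losses for _, r in evals])
        parent_idx = epsilon_lexicase_select(L, cfg.pop_size, rng, cfg.epsilon_mode)
        parent_reps = [pop[i] for i in parent_idx]
        offspring = vary(parent_reps, ctx, rng, diagnostics)
        off_evals = [ctx.evaluate_candidate(r) for r in offspring]
        for model, record in off_evals:
            archive.update(model, record)
        combined = pop + offspring
        combined_evals = evals + off_evals
        objectives = np.array(
            [(r.balanced_loss, r.complexity) for _, r in combined_evals]
        )
        surv = nsga2_survive(objectives, cfg.pop_size, rng)
        pop = [combined[i] for i in surv]
        evals = [combined_evals[i] for i in surv]
        log_generation(gen)

    if cfg.post_run_simplify:
        simplified = ParetoArchive()
        for model, _ in archive.members:
            slim = simplify_post_run(
                model,
                train.X,
                train.y,
                tolerance=cfg.simplify_tolerance,
                rng=rng,
                ridge=cfg.ridge,
                operator_weights=cfg.operator_weights,
            )
            model2, record = ctx.evaluate_candidate(slim.representation)
            simplified.update(model2, record)
        archive = simplified

    final = select_final(archive, val)
    final.training_meta = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_train": train.n,
        "n_validation": val.n,
        "diagnostics": diagnostics,
    }
    return archive, final, history
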