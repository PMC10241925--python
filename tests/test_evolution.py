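import numpy as np
import pytest
from scipy.stats import chisquare, spearmanr

from boolfeat import expressions as ex
from boolfeat.datasets import Dataset
from boolfeat.evolution import (
    EvolutionConfig,
    _SearchContext,
    epsilon_lexicase_select,
    fast_non_dominated_sort,
    init_population,
    nsga2_survive,
    run,
    univariate_feature_weights,
    vary,
)
from boolfeat.exceptions import ConfigError, DegenerateDataError
from boolfeat.metrics import auroc
from boolfeat.selection import validation_loss
from boolfeat.synthetic import SyntheticSpec, make_planted_rule


class TestConfig:
    def test_rates_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            EvolutionConfig(variation_rates={"insertion": 0.5, "deletion": 0.2,
                                             "point": 0.1, "crossover": 0.1,
                                             "correlation_deletion": 0.0})

    def test_tiny_population_rejected(self):
        with pytest.raises(ConfigError):
            EvolutionConfig(pop_size=2)


class TestUnivariateWeights:
    def test_label_identical_feature_dominates(self, rng):
        y = np.tile([0, 1], 50)
        X = rng.normal(size=(100, 4))
        X[:, 2] = y + rng.normal(0, 1e-3, 100)
        ds = Dataset(X=X, y=y, feature_names=list("abcd"),
                     subject_ids=[str(i) for i in range(100)])
        w = univariate_feature_weights(ds)
        assert np.argmax(w) == 2
        assert w.sum() == pytest.approx(1.0)

    def test_noise_feature_gets_small_weight(self):
        rng = np.random.default_rng(5)
        n, d = 2000, 5
        X = rng.normal(size=(n, d))
        y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(int)  # features 2-4 pure noise
        ds = Dataset(X=X, y=y, feature_names=[f"x{j}" for j in range(d)],
                     subject_ids=[str(i) for i in range(n)])
        w = univariate_feature_weights(ds)
        assert np.all(w[2:] < 2 / d)

    def test_permutation_equivariance(self, small_dataset):
        w = univariate_feature_weights(small_dataset)
        perm = np.array([3, 1, 0, 5, 4, 2])
        permuted = Dataset(X=small_dataset.X[:, perm], y=small_dataset.y,
                           feature_names=[small_dataset.feature_names[j] for j in perm],
                           subject_ids=small_dataset.subject_ids)
        np.testing.assert_allclose(univariate_feature_weights(permuted), w[perm],
                                   atol=1e-8)


class TestInitPopulation:
    def test_single_feature_dataset(self, rng):
        X = rng.normal(size=(60, 1))
        ds = Dataset(X=X, y=(X[:, 0] > 0).astype(int), feature_names=["only"],
                     subject_ids=[str(i) for i in range(60)])
        cfg = EvolutionConfig(pop_size=10, generations=1)
        pop = init_population(ds, cfg, np.random.default_rng(0))
        for rep in pop:
            for tree in rep.trees:
                for n in tree.walk():
                    if n.feature_index is not None:
                        assert n.feature_index == 0

    def test_deterministic(self, small_dataset):
        cfg = EvolutionConfig(pop_size=20, generations=1)
        ctx = _SearchContext(small_dataset, cfg)
        a = init_population(small_dataset, cfg, np.random.default_rng(7), ctx)
        b = init_population(small_dataset, cfg, np.random.default_rng(7), ctx)
        assert a == b

    def test_all_candidates_valid(self, small_dataset):
        cfg = EvolutionConfig(pop_size=40, generations=1)
        ctx = _SearchContext(small_dataset, cfg)
        for rep in init_population(small_dataset, cfg, np.random.default_rng(1), ctx):
            assert ex.validate(rep, small_dataset.d, cfg.max_dim, cfg.max_depth) == []

    def test_sampling_tracks_feature_weights(self, small_dataset):
        cfg = EvolutionConfig(pop_size=20, generations=1)
        ctx = _SearchContext(small_dataset, cfg)
        counts = np.zeros(small_dataset.d)
        rng = np.random.default_rng(3)
        for _ in range(100):
            for rep in init_population(small_dataset, cfg, rng, ctx):
                for tree in rep.trees:
                    for n in tree.walk():
                        if n.feature_index is not None:
                            counts[n.feature_index] += 1
        rho, _ = spearmanr(counts, ctx.feature_weights)
        assert rho > 0.8


class TestEpsilonLexicase:
    def test_strictly_best_always_selected(self, rng):
        L = np.array([[0.1, 0.1], [0.5, 0.5], [0.9, 0.3]])
        picks = epsilon_lexicase_select(L, 50, rng, epsilon_mode="zero")
        assert set(picks) == {0}

    def test_identical_candidates_uniform(self):
        rng = np.random.default_rng(11)
        L = np.ones((4, 6))
        picks = epsilon_lexicase_select(L, 10_000, rng)
        _, p = chisquare(np.bincount(picks, minlength=4))
        assert p > 0.01

    def test_matches_enumeration_oracle(self):
        """3 candidates x 2 cases: exact selection probabilities by
        enumerating case orders and survivor filtering."""
        L = np.array([[0.0, 0.9], [0.8, 0.0], [0.35, 0.9]])

        def survivors(order):
            surv = list(range(3))
            for c in order:
                col = np.array([L[i, c] for i in surv])
                elite = col.min()
                eps = np.median(np.abs(col - np.median(col)))
                surv = [i for i, v in zip(surv, col) if v <= elite + eps]
                if len(surv) == 1:
                    break
            return surv

        expected = np.zeros(3)
        for order in ([0, 1], [1, 0]):
            surv = survivors(order)
            for i in surv:
                expected[i] += 0.5 / len(surv)

        rng = np.random.default_rng(0)
        picks = epsilon_lexicase_select(L, 20_000, rng)
        freq = np.bincount(picks, minlength=3) / 20_000
        np.testing.assert_allclose(freq, expected, atol=0.02)

    def test_empty_population_errors(self, rng):
        with pytest.raises(ValueError):
            epsilon_lexicase_select(np.empty((0, 3)), 1, rng)


class TestVary:
    def test_fuzz_all_offspring_valid(self, small_dataset):
        cfg = EvolutionConfig(pop_size=20, generations=1)
        ctx = _SearchContext(small_dataset, cfg)
        rng = np.random.default_rng(0)
        parents = init_population(small_dataset, cfg, rng, ctx)
        for _ in range(150):  # 150 rounds x 20 parents = 3000 variations
            offspring = vary(parents, ctx, rng)
            for child in offspring:
                assert ex.validate(child, small_dataset.d, cfg.max_dim,
                                   cfg.max_depth) == []
            parents = offspring

    def test_deletion_never_empties_representation(self, small_dataset):
        cfg = EvolutionConfig(
            pop_size=4, generations=1,
            variation_rates={"insertion": 0, "deletion": 1.0, "point": 0,
                             "crossover": 0, "correlation_deletion": 0},
        )
        ctx = _SearchContext(small_dataset, cfg)
        rng = np.random.default_rng(2)
        parents = [ex.Representation((ex.feature(0),))] * 4
        for child in vary(parents, ctx, rng):
            assert child.p >= 1


class TestNsga2:
    def test_dominated_candidate_excluded(self, rng):
        obj = np.array([[1.0, 1.0], [2.0, 2.0], [1.0, 2.0]])
        surv = nsga2_survive(obj, 2, rng)
        assert 1 not in surv

    def test_fronts_match_brute_force(self, rng):
        for _ in range(20):
            obj = rng.integers(0, 8, size=(50, 2)).astype(float)
            fronts = fast_non_dominated_sort(obj)
            rank = np.empty(50, dtype=int)
            for f, front in enumerate(fronts):
                rank[front] = f
            # brute force: peel non-dominated layers by pairwise scan
            remaining = set(range(50))
            level = 0
            while remaining:
                front = {
                    i for i in remaining
                    if not any(
                        (obj[j, 0] <= obj[i, 0] and obj[j, 1] <= obj[i, 1]
                         and (obj[j, 0] < obj[i, 0] or obj[j, 1] < obj[i, 1]))
                        for j in remaining
                    )
                }
                for i in front:
                    assert rank[i] == level
                remaining -= front
                level += 1

    def test_identical_objectives_seeded_subset(self):
        obj = np.ones((30, 2))
        a = nsga2_survive(obj, 10, np.random.default_rng(5))
        b = nsga2_survive(obj, 10, np.random.default_rng(5))
        assert len(a) == 10
        np.testing.assert_array_equal(a, b)


@pytest.fixture(scope="module")
def planted():
    rule = ex.Representation((ex.gt(0, 0.5),))
    spec = SyntheticSpec(n=400, d=8, rule=rule, seed=2)
    return make_planted_rule(spec)[0]


class TestRun:
    def _cfg(self, **kw):
        base = dict(pop_size=30, generations=8, seed=0)
        base.update(kw)
        return EvolutionConfig(**base)

    def test_recovers_single_threshold_rule(self, planted):
        archive, model, history = run(planted, self._cfg(generations=15))
        assert auroc(planted.y, model.predict_proba(planted)) >= 0.99
        assert model.size <= 6

    def test_deterministic(self, planted):
        a = run(planted, self._cfg())
        b = run(planted, self._cfg())
        assert a[1].to_dict() == b[1].to_dict()
        assert [r.balanced_loss for _, r in a[0].members] == \
               [r.balanced_loss for _, r in b[0].members]

    def test_population_best_loss_non_increasing(self, planted):
        _, _, history = run(planted, self._cfg())
        best = [h["best_loss"] for h in history]
        assert all(b2 <= b1 + 1e-12 for b1, b2 in zip(best, best[1:]))

    def test_archive_mutually_non_dominated(self, planted):
        archive, _, _ = run(planted, self._cfg())
        objs = [(r.balanced_loss, r.complexity) for _, r in archive.members]
        for i, a in enumerate(objs):
            for j, b in enumerate(objs):
                if i != j:
                    assert not (a[0] <= b[0] and a[1] <= b[1]
                                and (a[0] < b[0] or a[1] < b[1]))

    def test_max_dim_one_constrains_every_archived_model(self, planted):
        archive, model, _ = run(planted, self._cfg(max_dim=1))
        assert model.representation.p == 1
        assert all(m.representation.p == 1 for m in archive.models)

    def test_zero_generations_selects_best_initial_candidate(self, planted):
        from boolfeat.datasets import split_train_validation

        cfg = self._cfg(generations=0)
        archive, model, history = run(planted, cfg)
        assert len(history) == 1
        _, val = split_train_validation(planted, cfg.validation_frac, cfg.seed)
        losses = [validation_loss(m, val) for m in archive.models]
        assert validation_loss(model, val) == pytest.approx(min(losses))
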