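import numpy as np
import pytest

from boolfeat import expressions as ex
from boolfeat.datasets import Dataset
from boolfeat.synthetic import SyntheticSpec, make_planted_rule


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_dataset(rng):
    """120 subjects, 6 features, labels driven by x0 > 0 with some noise."""
    X = rng.normal(size=(120, 6))
    y = ((X[:, 0] > 0) ^ (rng.random(120) < 0.1)).astype(int)
    return Dataset(
        X=X,
        y=y,
        feature_names=[f"x{j}" for j in range(6)],
        subject_ids=[f"s{i}" for i in range(120)],
    )


@pytest.fixture(scope="session")
def planted_and_dataset():
    """Noise-free labels from a planted two-term AND rule."""
    rule = ex.Representation((ex.and_(ex.gt(0, 0.5), ex.gt(1, -0.3)),))
    spec = SyntheticSpec(n=1000, d=10, rule=rule, seed=3)
    ds, truth = make_planted_rule(spec)
    return ds, truth


def random_node(rng, d, depth, boolean=True):
    """Random well-typed tree for fuzzing (Boolean grammar only)."""
    if boolean:
        if depth <= 1 or rng.random() < 0.4:
            kind = ex.LT if rng.random() < 0.5 else ex.GT
            return ex.Node(kind, feature_index=int(rng.integers(d)),
                           threshold=float(rng.normal()))
        k = rng.random()
        if k < 0.25:
            return ex.not_(random_node(rng, d, depth - 1))
        kind = ex.AND if k < 0.625 else ex.OR
        return ex.Node(kind, children=(random_node(rng, d, depth - 1),
                                       random_node(rng, d, depth - 1)))
    return ex.feature(int(rng.integers(d)))


def random_representation(rng, d, max_p=4, max_depth=3):
    p = int(rng.integers(1, max_p + 1))
    trees = []
    for _ in range(p):
        boolean = rng.random() < 0.8
        trees.append(random_node(rng, d, int(rng.integers(1, max_depth + 1)), boolean))
    return ex.Representation(tuple(trees))
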