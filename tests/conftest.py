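import numpy as np
import pytest

from conclust import AlgorithmSpec, ClusterAssignment, ExpressionMatrix


@pytest.fixture
def two_clouds() -> ExpressionMatrix:
    """Two well-separated point clouds of 10 rows each."""
    rng = np.random.default_rng(42)
    a = rng.normal(0.0, 0.05, size=(10, 3))
    b = rng.normal(5.0, 0.05, size=(10, 3))
    values = np.vstack([a, b])
    return ExpressionMatrix(values, [f"g{i}" for i in range(20)],
                            ["c1", "c2", "c3"])


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    return ExpressionMatrix(
        np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        ["a", "b", "c"], ["x", "y"],
    )


def random_consensus_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random symmetric matrix in [0,1] with unit diagonal."""
    m = rng.uniform(size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    return m


def random_assignment(ids, k: int, rng: np.random.Generator) -> ClusterAssignment:
    """Random partition of ids into k non-empty clusters."""
    n = len(ids)
    labels = np.concatenate([np.arange(1, k + 1),
                             rng.integers(1, k + 1, size=n - k)])
    rng.shuffle(labels)
    return ClusterAssignment(dict(zip(ids, labels.tolist())), k,
                             AlgorithmSpec("reference"))
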