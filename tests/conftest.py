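import numpy as np
import pytest

from gtomnet import AdjacencyMatrix, ExpressionMatrix


@pytest.fixture
def path_graph() -> AdjacencyMatrix:
    """The 3-node path 1–2–3 (indices 0–1–2)."""
    a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=int)
    return AdjacencyMatrix(values=a, cutoff=0.7, entity_ids=["n1", "n2", "n3"])


@pytest.fixture
def tiny_expression() -> ExpressionMatrix:
    """3 genes × 4 samples with hand-computable correlations."""
    values = np.array([[1, 2, 3, 4], [4, 3, 2, 1], [1, 3, 2, 4]], dtype=float)
    return ExpressionMatrix(values, ["g1", "g2", "g3"], ["s1", "s2", "s3", "s4"])


def random_adjacency(rng: np.random.Generator, n: int, p: float) -> AdjacencyMatrix:
    """Erdős–Rényi adjacency for oracle comparisons."""
    upper = rng.random((n, n)) < p
    a = np.triu(upper, 1)
    a = (a | a.T).astype(int)
    return AdjacencyMatrix(values=a, cutoff=0.5, entity_ids=[f"n{i}" for i in range(n)])
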