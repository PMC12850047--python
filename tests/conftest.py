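import numpy as np
import pandas as pd
import pytest

from kinnet.coexpression import AdjacencyGraph, ModulePartition


def make_adjacency(weights: np.ndarray, genes=None, power: float = 1.0) -> AdjacencyGraph:
    """Wrap a hand-set symmetric weight matrix as an AdjacencyGraph."""
    n = weights.shape[0]
    genes = genes or [f"g{i}" for i in range(n)]
    w = np.asarray(weights, dtype=float)
    np.fill_diagonal(w, 0.0)
    return AdjacencyGraph(weights=pd.DataFrame(w, index=genes, columns=genes), power=power)


def make_partition(mapping: dict) -> ModulePartition:
    return ModulePartition(labels=pd.Series(mapping))


@pytest.fixture
def correlated_pair():
    """Two 10-sample vectors with sample Pearson correlation exactly 0.8."""
    n = 10
    u = np.zeros(n)
    u[: n // 2] = 1.0
    u = (u - u.mean()) / np.linalg.norm(u - u.mean())
    v = np.zeros(n)
    v[::2] = 1.0
    v = v - v.mean()
    v -= (v @ u) * u
    v /= np.linalg.norm(v)
    rho = 0.8
    y = rho * u + np.sqrt(1 - rho**2) * v
    assert abs(np.corrcoef(u, y)[0, 1] - rho) < 1e-12
    return u, y
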