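import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from subcovnet import AnalysisConfig, CohortSpec, NodeSet, generate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """One draw of the calibrated 180-subject synthetic cohort."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def nodes17() -> NodeSet:
    return NodeSet(tuple(f"n{i:02d}" for i in range(17)))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def fast_config() -> AnalysisConfig:
    """Desk-scale settings for tests that exercise the permutation chain."""
    return AnalysisConfig(n_permutations=99, n_random=5)


def correlated_volumes(
    rng: np.random.Generator,
    node_set: NodeSet,
    n_subjects: int = 40,
    correlation: np.ndarray | float = 0.4,
) -> pd.DataFrame:
    """Multivariate-normal volume table over a node set (test helper)."""
    p = len(node_set)
    if np.isscalar(correlation):
        C = np.full((p, p), float(correlation))
        np.fill_diagonal(C, 1.0)
    else:
        C = np.asarray(correlation, dtype=float)
    L = np.linalg.cholesky(C)
    X = rng.standard_normal((n_subjects, p)) @ L.T
    return pd.DataFrame(X, columns=list(node_set))


def random_adjacency(
    rng: np.random.Generator, n: int, n_edges: int | None = None
) -> np.ndarray:
    """Uniform random simple graph with a given edge count."""
    iu, ju = np.triu_indices(n, k=1)
    m = iu.size
    if n_edges is None:
        n_edges = int(rng.integers(1, m + 1))
    pick = rng.choice(m, size=n_edges, replace=False)
    adj = np.zeros((n, n), dtype=int)
    adj[iu[pick], ju[pick]] = 1
    return adj + adj.T
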