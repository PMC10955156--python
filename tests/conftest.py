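import numpy as np
import pytest

from hetdti.hetnet_io import BipartiteAssociation, NodeRegistry, SimilarityMatrix
from hetdti.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def dataset():
    """Default planted synthetic dataset (the packaged study conditions)."""
    return generate(SyntheticConfig())


@pytest.fixture(scope="session")
def null_dataset():
    """No-structure control: every network independent of the labels."""
    return generate(SyntheticConfig(planted=False))


@pytest.fixture
def small_dataset():
    """Fast fixture for pipeline smoke tests."""
    return generate(SyntheticConfig(n_drugs=20, n_proteins=25, n_diseases=10,
                                    n_side_effects=8, latent_rank=2, seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_similarity(rng: np.random.Generator, n: int, name: str = "rand") -> SimilarityMatrix:
    """Random valid similarity matrix: symmetric, [0,1], unit diagonal."""
    M = rng.random((n, n))
    M = (M + M.T) / 2.0
    return SimilarityMatrix("drug", M, name=name)


def random_binary_assoc(rng: np.random.Generator, n: int, m: int,
                        density: float = 0.3) -> BipartiteAssociation:
    return BipartiteAssociation("drug", "disease", (rng.random((n, m)) < density).astype(float))


def make_registry(node_type: str, prefix: str, n: int) -> NodeRegistry:
    return NodeRegistry(node_type, [f"{prefix}{i}" for i in range(n)])
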