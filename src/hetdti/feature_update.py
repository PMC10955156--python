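"""Spectral graph-convolution layer over similarity networks.

A single dimension-preserving layer per node type:

    H = sigma( Ahat X W ),    Ahat = Dtilde^{-1/2} (A + I) Dtilde^{-1/2},

where A is a similarity network of that node type, the added identity is the
self-loop, and Dtilde is the degree diagonal of A + I. This symmetric
normalization (all eigenvalues in [-1, 1]) is distinct from the row
normalization used for the random walk; both live side by side on purpose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .exceptions import ConfigurationError
from .hetnet_io import SimilarityMatrix
from .similarity import SimilarityInventory

ACTIVATIONS: dict[str, tuple[Callable[[np.ndarray], np.ndarray], Callable[[np.ndarray], np.ndarray]]] = {
    # name -> (sigma, sigma' as a function of the pre-activation z)
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)),
    "sigmoid": (
        lambda z: 1.0 / (1.0 + np.exp(-z)),
        lambda z: (s := 1.0 / (1.0 + np.exp(-z))) * (1.0 - s),
    ),
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
}


@dataclass
class NormalizedAdjacency:
    """Self-loop symmetric-normalized adjacency Dtilde^{-1/2}(A+I)Dtilde^{-1/2}."""

    matrix: np.ndarray

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class GcnLayerParams:
    """Trainable weight matrix and activation of one graph-convolution layer."""

    weight: np.ndarray
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.activation not in ACTIVATIONS:
            raise ConfigurationError(
                f"unknown activation {self.activation!r}; expected one of {sorted(ACTIVATIONS)}"
            )
        self.weight = np.asarray(self.weight, dtype=float)
        if not np.isfinite(self.weight).all():
            raise ValueError("GCN weight matrix must be finite")


def normalize_adjacency(sim: SimilarityMatrix) -> NormalizedAdjacency:
    """Add self-loops and symmetric-normalize a similarity network."""
    A = sim.matrix
    A_tilde = A + np.eye(A.shape[0])
    d = A_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return NormalizedAdjacency(inv_sqrt[:, None] * A_tilde * inv_sqrt[None, :])


def init_gcn_params(
    in_dim: int,
    out_dim: int | None = None,
    activation: str = "relu",
    seed: int | None = None,
) -> GcnLayerParams:
    """Glorot-uniform initialized layer; output width defaults to input width."""
    out_dim = in_dim if out_dim is None else out_dim
    rng = np.random.default_rng(seed)
    limit = np.sqrt(6.0 / (in_dim + out_dim))
    return GcnLayerParams(rng.uniform(-limit, limit, size=(in_dim, out_dim)), activation)


def gcn_layer(adj: NormalizedAdjacency, X: np.ndarray, params: GcnLayerParams) -> np.ndarray:
    """Forward pass H = sigma(Ahat X W)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] != adj.n:
        raise ValueError(f"feature rows {X.shape[0]} do not match adjacency size {adj.n}")
    if X.shape[1] != params.weight.shape[0]:
        raise ValueError(
            f"feature width {X.shape[1]} does not match weight input dim {params.weight.shape[0]}"
        )
    act, _ = ACTIVATIONS[params.activation]
    return act(adj.matrix @ X @ params.weight)


def build_gcn_adjacency(
    inventory: SimilarityInventory, node_type: str, mode: str = "mean"
) -> NormalizedAdjacency:
    """Pick the similarity network the convolution runs on.

    ``mean`` (default): elementwise mean of all of the type's similarity
    networks. ``primary``: the precomputed similarity only (chemical for
    drugs, sequence for proteins) — by convention the first inventory member.
    """
    networks = inventory.for_type(node_type)
    if not networks:
        raise ConfigurationError(f"empty similarity inventory for {node_type!r}")
    if mode == "mean":
        M = np.mean([s.matrix for s in networks], axis=0)
    elif mode == "primary":
        M = networks[0].matrix
    else:
        raise ConfigurationError(f"unknown adjacency mode {mode!r} (expected mean|primary)")
    return normalize_adjacency(SimilarityMatrix(node_type, M, name=f"gcn_{mode}({node_type})"))
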