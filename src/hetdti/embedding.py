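"""Diffusion component analysis: SVD embedding of log diffusion states.

Each network's diffusion-state matrix S is smoothed and log-transformed,
L = log(S + pseudocount), and the node features X are the best rank-d
factorization X W^T ~ L in Frobenius norm. For K networks of the same node
type the feature matrix X is shared while each network keeps its own context
matrix W^r; the joint objective

    sum_r || X (W^r)^T - L^r ||_F^2

is minimized exactly by the SVD of the horizontal concatenation [L^1 ... L^K]
(Eckart-Young applied to the stacked least-squares problem), with the
singular values split symmetrically: X = U_d S_d^{1/2}, W^r the r-th n-row
block of V_d S_d^{1/2}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diffusion import (
    DEFAULT_MAX_ITER,
    DEFAULT_RESTART_PROB,
    DEFAULT_TOL,
    DiffusionState,
    diffuse_all,
)
from .hetnet_io import SimilarityMatrix

#: default feature widths per node type, the best-performing setting of the
#: original study's dimension grid (drugs 80-200, proteins 200-400)
DEFAULT_D_DRUG = 200
DEFAULT_D_PROTEIN = 400


@dataclass
class LogDiffusionMatrix:
    """Elementwise log of a smoothed diffusion-state matrix."""

    matrix: np.ndarray
    pseudocount: float


@dataclass
class EmbeddingPair:
    """Shared node features X plus per-network context features W.

    ``features[i]`` is the d-dimensional signature of node i; ``contexts[r]``
    holds the network-specific context rows w_j of network r, so that
    ``features @ contexts[r].T`` reconstructs the r-th log diffusion matrix.
    """

    features: np.ndarray
    contexts: list[np.ndarray]
    d: int
    singular_values: np.ndarray


def log_diffusion(state: DiffusionState, pseudocount: float) -> LogDiffusionMatrix:
    """L = log(S + pseudocount); the pseudocount keeps zero entries finite."""
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    return LogDiffusionMatrix(np.log(state.matrix + pseudocount), pseudocount)


def _svd_embed(C: np.ndarray, d: int, n: int, k: int) -> EmbeddingPair:
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    X = U[:, :d] * np.sqrt(s[:d])
    V = Vt[:d].T * np.sqrt(s[:d])  # (k*n) x d
    # deterministic sign convention: largest-|.| entry of each X column positive
    for c in range(d):
        j = np.argmax(np.abs(X[:, c]))
        if X[j, c] < 0:
            X[:, c] = -X[:, c]
            V[:, c] = -V[:, c]
    contexts = [V[r * n:(r + 1) * n] for r in range(k)]
    return EmbeddingPair(features=X, contexts=contexts, d=d, singular_values=s[:d].copy())


def clusdca_single(L: LogDiffusionMatrix, d: int) -> EmbeddingPair:
    """Rank-d SVD factorization of one log diffusion matrix.

    X = U_d S_d^{1/2}, W = V_d S_d^{1/2}; X W^T is the Frobenius-optimal
    rank-d approximation of L.
    """
    n = L.matrix.shape[0]
    if not 1 <= d <= n:
        raise ValueError(f"embedding dimension d={d} must be in [1, {n}]")
    return _svd_embed(L.matrix, d, n, 1)


def clusdca_multi(Ls: list[LogDiffusionMatrix], d: int) -> EmbeddingPair:
    """Shared-feature factorization of K log diffusion matrices.

    Exact closed form: the stacked objective equals the single-matrix
    objective on the n x Kn concatenation, so one SVD solves it.
    """
    if not Ls:
        raise ValueError("need at least one log diffusion matrix")
    n = Ls[0].matrix.shape[0]
    for L in Ls:
        if L.matrix.shape != (n, n):
            raise ValueError("all log diffusion matrices must be square with equal size")
    if not 1 <= d <= n:
        raise ValueError(f"embedding dimension d={d} must be in [1, {n}]")
    C = np.hstack([L.matrix for L in Ls])
    return _svd_embed(C, d, n, len(Ls))


def reconstruction_error(pair: EmbeddingPair, Ls: list[LogDiffusionMatrix]) -> float:
    """Objective value sum_r ||X (W^r)^T - L^r||_F^2 at the embedding."""
    return float(
        sum(
            np.linalg.norm(pair.features @ W.T - L.matrix, "fro") ** 2
            for W, L in zip(pair.contexts, Ls)
        )
    )


def embed_node_type(
    networks: list[SimilarityMatrix],
    d: int,
    p: float = DEFAULT_RESTART_PROB,
    pseudocount: float | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    backend: str = "iterative",
) -> EmbeddingPair:
    """RWR -> log transform -> shared SVD embedding for one node type.

    ``pseudocount`` defaults to 1/n, the standard diffusion-state smoothing.
    ``d`` is capped at the number of nodes (rank-d of an n x Kn matrix cannot
    exceed n), so small synthetic networks can run with the large real-data
    default widths.
    """
    if not networks:
        raise ValueError("need at least one similarity network")
    n = networks[0].n
    if pseudocount is None:
        pseudocount = 1.0 / n
    d_eff = min(d, n)
    states = diffuse_all(networks, p=p, tol=tol, max_iter=max_iter, backend=backend)
    Ls = [log_diffusion(s, pseudocount) for s in states]
    return clusdca_multi(Ls, d_eff)


def write_embedding(pair: EmbeddingPair, ids: list[str], path) -> None:
    """Dump features as TSV: node_id followed by d feature columns."""
    with open(path, "w") as fh:
        for nid, row in zip(ids, pair.features):
            fh.write(nid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
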