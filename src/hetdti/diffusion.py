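"""Random walk with restart (RWR) diffusion states.

For each similarity network A, the one-step transition matrix is the
row-normalization Ahat = D^-1 A (D the row-sum diagonal). The diffusion
state of node i is the stationary distribution of the restart walk

    r^{t+1} = (1 - p) r^t Ahat + p r^0,      r^0 = e_i,

computed for all seeds at once by iterating the full matrix from R^0 = I.
Row-vector convention throughout: rows of the diffusion-state matrix are the
per-seed distributions, and propagation multiplies on the right by Ahat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import NumericalError
from .hetnet_io import SimilarityMatrix

logger = logging.getLogger(__name__)

DEFAULT_RESTART_PROB = 0.5
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 1000


@dataclass
class TransitionMatrix:
    """Row-stochastic one-step transition matrix of a similarity network."""

    matrix: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if (M < 0).any():
            raise NumericalError(f"negative transition probability in {self.source!r}")
        rows = M.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-10):
            raise NumericalError(f"transition matrix {self.source!r} rows do not sum to 1")
        self.matrix = M

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class DiffusionState:
    """n x n matrix whose row i is the RWR stationary distribution seeded at i."""

    matrix: np.ndarray
    restart_prob: float
    iterations_used: int
    converged: bool
    source: str = ""


def transition_matrix(sim: SimilarityMatrix) -> TransitionMatrix:
    """Row-normalize a similarity matrix: Ahat = D^-1 A.

    Row sums are strictly positive because similarity matrices carry a unit
    diagonal; a zero row would indicate an upstream validation failure.
    """
    A = sim.matrix
    d = A.sum(axis=1)
    if (d <= 0).any():
        raise NumericalError(f"degenerate zero row in similarity network {sim.name!r}")
    return TransitionMatrix(A / d[:, None], source=sim.name)


def rwr(
    trans: TransitionMatrix,
    p: float = DEFAULT_RESTART_PROB,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> DiffusionState:
    """Iterate the restart walk to its fixed point for every seed node.

    Stops when the maximum row L1 change falls below ``tol``. Because the map
    is a contraction with factor (1 - p), convergence is geometric for any
    p > 0; hitting ``max_iter`` logs a warning and sets ``converged=False``
    rather than raising.
    """
    if not 0 < p <= 1:
        raise ValueError(f"restart probability must be in (0, 1], got {p}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    n = trans.n
    A = trans.matrix
    R0 = np.eye(n)
    R = R0.copy()
    decay = 1.0 - p
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        R_next = decay * (R @ A) + p * R0
        delta = np.abs(R_next - R).sum(axis=1).max()
        R = R_next
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "RWR on %r did not converge in %d iterations (p=%g)", trans.source, max_iter, p
        )
    return DiffusionState(R, restart_prob=p, iterations_used=it, converged=converged,
                          source=trans.source)


def rwr_closed_form(trans: TransitionMatrix, p: float = DEFAULT_RESTART_PROB) -> DiffusionState:
    """Exact diffusion states by linear solve: R = p (I - (1-p) Ahat)^-1.

    The fixed point of r = (1-p) r Ahat + p e_i is r (I - (1-p)Ahat) = p e_i;
    stacking all seeds gives the matrix identity above. The system matrix is
    strictly diagonally dominant for p > 0 and row-stochastic Ahat, hence
    nonsingular. Exact up to solver precision; intended for small networks
    and as the test oracle for the iterative backend.
    """
    if not 0 < p <= 1:
        raise ValueError(f"restart probability must be in (0, 1], got {p}")
    n = trans.n
    M = np.eye(n) - (1.0 - p) * trans.matrix
    try:
        # r M = p e_i for every seed i  <=>  M^T R^T = p I
        R = p * np.linalg.solve(M.T, np.eye(n)).T
    except np.linalg.LinAlgError as exc:
        raise NumericalError("singular RWR system") from exc
    return DiffusionState(R, restart_prob=p, iterations_used=0, converged=True,
                          source=trans.source)


def diffuse_all(
    networks: list[SimilarityMatrix],
    p: float = DEFAULT_RESTART_PROB,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    backend: str = "iterative",
) -> list[DiffusionState]:
    """Diffusion state of every network in an inventory list."""
    if backend == "iterative":
        return [rwr(transition_matrix(s), p=p, tol=tol, max_iter=max_iter) for s in networks]
    if backend == "closed_form":
        return [rwr_closed_form(transition_matrix(s), p=p) for s in networks]
    raise ValueError(f"unknown diffusion backend {backend!r}")
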