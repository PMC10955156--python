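"""Bilinear decoder and the training loop.

The interaction score of drug i and protein j is the bilinear form of their
(optionally graph-convolved) features through two projection matrices:

    Yhat = H_drug D P^T H_protein^T,    D in R^{h_d x k}, P in R^{h_p x k}.

Training minimizes the squared reconstruction error of the edge weights,

    L(theta) = sum_{(i,j) in mask} (y_ij - yhat_ij)^2,

over the decoder projections and (when the feature-update layer is enabled)
the two GCN weight matrices, full batch, with analytic gradients. The
objective is quartic in the parameters and its curvature scales with the
feature magnitudes, so the default optimizer is adaptive-moment (Adam),
which is insensitive to that scale; plain gradient descent is available
(``optimizer="gd"``), stepping along the gradient of the mean over masked
entries — the same minimizer as the sum, with a step size that does not have
to shrink as the matrix grows. The reported loss trace is always the summed
squared error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .exceptions import NumericalError
from .feature_update import ACTIVATIONS, GcnLayerParams, NormalizedAdjacency, init_gcn_params

DEFAULT_LR = 0.01
DEFAULT_EPOCHS = 500


@dataclass
class DecoderParams:
    """Projection matrices of the bilinear decoder."""

    drug_proj: np.ndarray    # h_d x k
    protein_proj: np.ndarray  # h_p x k

    @property
    def k(self) -> int:
        return self.drug_proj.shape[1]


@dataclass
class ScoreMatrix:
    """Reconstructed drug x protein interaction scores."""

    matrix: np.ndarray


@dataclass
class TrainMask:
    """Binary matrix marking the pairs that contribute to the loss.

    Held-out test pairs must be 0; cross-validation constructs these masks
    from its fold splits and asserts the exclusion.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if not np.isin(np.unique(M), (0.0, 1.0)).all():
            raise ValueError("train mask must be binary")
        self.matrix = M


@dataclass
class TrainConfig:
    """Hyperparameters of the gradient-descent fit."""

    lr: float = DEFAULT_LR
    epochs: int = DEFAULT_EPOCHS
    k: Optional[int] = None          # decoder projection width; default min(h_d, h_p)
    optimizer: str = "adam"          # adam | gd
    seed: int = 0
    gcn_enabled: bool = True
    activation: str = "relu"
    weight_decay: float = 0.0


@dataclass
class ModelParams:
    """Everything gradient descent touches, plus the config that produced it."""

    decoder: DecoderParams
    gcn_drug: Optional[GcnLayerParams]
    gcn_protein: Optional[GcnLayerParams]
    config: TrainConfig = field(default_factory=TrainConfig)


def score_matrix(H_drug: np.ndarray, H_protein: np.ndarray, params: DecoderParams) -> ScoreMatrix:
    """Yhat = H_drug D P^T H_protein^T."""
    H_drug = np.atleast_2d(np.asarray(H_drug, dtype=float))
    H_protein = np.atleast_2d(np.asarray(H_protein, dtype=float))
    if H_drug.shape[1] != params.drug_proj.shape[0]:
        raise ValueError(
            f"drug feature width {H_drug.shape[1]} != projection rows {params.drug_proj.shape[0]}"
        )
    if H_protein.shape[1] != params.protein_proj.shape[0]:
        raise ValueError(
            f"protein feature width {H_protein.shape[1]} != projection rows "
            f"{params.protein_proj.shape[0]}"
        )
    return ScoreMatrix(H_drug @ params.drug_proj @ params.protein_proj.T @ H_protein.T)


def reconstruction_loss(Y: np.ndarray, Y_rec: ScoreMatrix | np.ndarray,
                        mask: Optional[TrainMask | np.ndarray] = None) -> float:
    """Sum of squared errors over masked-in entries."""
    Yh = np.asarray(getattr(Y_rec, "matrix", Y_rec), dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.shape != Yh.shape:
        raise ValueError(f"label shape {Y.shape} != score shape {Yh.shape}")
    diff = Yh - Y
    if mask is not None:
        diff = diff * np.asarray(getattr(mask, "matrix", mask), dtype=float)
    return float(np.sum(diff * diff))


def _forward_backward(Y, M, Xd, Xp, Ad, Ap, dec: DecoderParams,
                      gd: Optional[GcnLayerParams], gp: Optional[GcnLayerParams]):
    """Loss and analytic gradients of the masked squared-error objective.

    Returns (sum_loss, grads) where grads has keys D, P and, when the GCN is
    active, Wd, Wp. Gradients are for the MEAN over masked entries.
    """
    n_mask = max(M.sum(), 1.0)
    if gd is not None:
        act, dact = ACTIVATIONS[gd.activation]
        Zd = Ad @ Xd @ gd.weight
        Hd = act(Zd)
    else:
        Hd = Xd
    if gp is not None:
        act_p, dact_p = ACTIVATIONS[gp.activation]
        Zp = Ap @ Xp @ gp.weight
        Hp = act_p(Zp)
    else:
        Hp = Xp

    D, P = dec.drug_proj, dec.protein_proj
    Yh = Hd @ D @ P.T @ Hp.T
    R = M * (Yh - Y)
    sum_loss = float(np.sum(R * R))
    G = (2.0 / n_mask) * R

    HpP = Hp @ P
    HdD = Hd @ D
    grads = {
        "D": Hd.T @ (G @ HpP),
        "P": Hp.T @ (G.T @ HdD),
    }
    if gd is not None:
        dHd = G @ HpP @ D.T
        dZd = dHd * dact(Zd)
        grads["Wd"] = (Ad @ Xd).T @ dZd
    if gp is not None:
        dHp = G.T @ HdD @ P.T
        dZp = dHp * dact_p(Zp)
        grads["Wp"] = (Ap @ Xp).T @ dZp
    return sum_loss, grads, Hd, Hp


class _Adam:
    def __init__(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for key, g in grads.items():
            m = self.m.setdefault(key, np.zeros_like(g))
            v = self.v.setdefault(key, np.zeros_like(g))
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(
    Y: np.ndarray,
    X_drug: np.ndarray,
    X_protein: np.ndarray,
    adj_drug: Optional[NormalizedAdjacency] = None,
    adj_protein: Optional[NormalizedAdjacency] = None,
    mask: Optional[TrainMask | np.ndarray] = None,
    config: Optional[TrainConfig] = None,
) -> tuple[ModelParams, ScoreMatrix, list[float]]:
    """Fit GCN weights and decoder projections; return params, scores, loss trace.

    ``mask`` marks the pairs supervising the loss (default: all pairs). With
    ``config.gcn_enabled`` the normalized adjacencies are required and the
    drug/protein features are refined through one graph-convolution layer
    before decoding; otherwise the decoder consumes the raw embeddings.
    The returned loss trace holds the summed squared error per epoch
    (epoch 0 = before any update).
    """
    cfg = config or TrainConfig()
    Y = np.asarray(Y, dtype=float)
    Xd = np.asarray(X_drug, dtype=float)
    Xp = np.asarray(X_protein, dtype=float)
    M = np.ones_like(Y) if mask is None else np.asarray(getattr(mask, "matrix", mask), dtype=float)
    if M.shape != Y.shape:
        raise ValueError(f"mask shape {M.shape} != label shape {Y.shape}")

    rng = np.random.default_rng(cfg.seed)
    if cfg.gcn_enabled:
        if adj_drug is None or adj_protein is None:
            raise ValueError("gcn_enabled requires drug and protein adjacencies")
        gd = init_gcn_params(Xd.shape[1], activation=cfg.activation,
                             seed=int(rng.integers(2**31)))
        gp = init_gcn_params(Xp.shape[1], activation=cfg.activation,
                             seed=int(rng.integers(2**31)))
    else:
        gd = gp = None
    h_d = Xd.shape[1]
    h_p = Xp.shape[1]
    k = cfg.k if cfg.k is not None else min(h_d, h_p)
    lim_d = np.sqrt(6.0 / (h_d + k))
    lim_p = np.sqrt(6.0 / (h_p + k))
    dec = DecoderParams(
        drug_proj=rng.uniform(-lim_d, lim_d, size=(h_d, k)),
        protein_proj=rng.uniform(-lim_p, lim_p, size=(h_p, k)),
    )

    params: dict[str, np.ndarray] = {"D": dec.drug_proj, "P": dec.protein_proj}
    if gd is not None:
        params["Wd"] = gd.weight
        params["Wp"] = gp.weight
    opt = _Adam(cfg.lr) if cfg.optimizer == "adam" else None
    if cfg.optimizer not in ("gd", "adam"):
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")

    trace: list[float] = []
    for epoch in range(cfg.epochs + 1):
        loss, grads, Hd, Hp = _forward_backward(Y, M, Xd, Xp,
                                                adj_drug.matrix if gd is not None else None,
                                                adj_protein.matrix if gp is not None else None,
                                                dec, gd, gp)
        if not np.isfinite(loss):
            raise NumericalError(
                f"non-finite loss at epoch {epoch}; try a smaller learning rate"
            )
        trace.append(loss)
        if epoch == cfg.epochs:
            break
        if cfg.weight_decay > 0:
            for key in grads:
                grads[key] = grads[key] + cfg.weight_decay * params[key]
        if opt is not None:
            opt.step(params, grads)
        else:
            for key, g in grads.items():
                params[key] -= cfg.lr * g

    final = score_matrix(Hd, Hp, dec)
    model = ModelParams(decoder=dec, gcn_drug=gd, gcn_protein=gp, config=replace(cfg))
    return model, final, trace


def predict(model: ModelParams, X_drug: np.ndarray, X_protein: np.ndarray,
            adj_drug: Optional[NormalizedAdjacency] = None,
            adj_protein: Optional[NormalizedAdjacency] = None) -> ScoreMatrix:
    """Score matrix of a fitted model on (possibly new) features."""
    if model.gcn_drug is not None:
        act, _ = ACTIVATIONS[model.gcn_drug.activation]
        Hd = act(adj_drug.matrix @ X_drug @ model.gcn_drug.weight)
    else:
        Hd = np.asarray(X_drug, dtype=float)
    if model.gcn_protein is not None:
        act, _ = ACTIVATIONS[model.gcn_protein.activation]
        Hp = act(adj_protein.matrix @ X_protein @ model.gcn_protein.weight)
    else:
        Hp = np.asarray(X_protein, dtype=float)
    return score_matrix(Hd, Hp, model.decoder)
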