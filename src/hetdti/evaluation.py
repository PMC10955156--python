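"""Evaluation protocol: negative sampling, stratified folds, ranking metrics,
redundancy filtering, and end-to-end cross-validation.

Known drug-target pairs are positives; a configurable multiple of unlabeled
pairs is sampled uniformly without replacement as negatives (1:1 and 1:10
are the standard settings). Ten-fold cross-validation holds out 10% of the
sampled pairs per fold; held-out pairs never reach the training mask, and —
because the label matrix is never an input to similarity construction or
diffusion — the node embeddings are structurally independent of the fold
split and are computed once per run.

AUROC uses the Mann-Whitney convention (ties get half credit); AUPR is the
step-wise, non-interpolated precision-recall integral. Both are delegated to
scikit-learn, which implements exactly these conventions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .embedding import DEFAULT_D_DRUG, DEFAULT_D_PROTEIN, embed_node_type
from .exceptions import ConfigurationError, DataValidationError
from .feature_update import build_gcn_adjacency
from .hetnet_io import HeterogeneousNetworkSet
from .reconstruction import TrainConfig, TrainMask, train
from .similarity import build_inventory

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {"drug": 0.6, "protein": 0.4}


@dataclass
class PairSample:
    """All positive pairs plus seeded sampled negatives."""

    pairs: list[tuple[int, int, int]]  # (drug index, protein index, label)
    ratio: float
    seed: int

    @property
    def positives(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j, y in self.pairs if y == 1]

    @property
    def negatives(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j, y in self.pairs if y == 0]


@dataclass
class FoldSplit:
    """Disjoint stratified folds over a pair sample."""

    folds: list[list[tuple[int, int, int]]]
    seed: int


@dataclass
class EvalReport:
    """Per-fold AUPR/AUROC with aggregates and the config that produced them."""

    fold_aupr: list[float]
    fold_auroc: list[float]
    config: dict = field(default_factory=dict)

    @property
    def mean_aupr(self) -> float:
        return float(np.mean(self.fold_aupr))

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.fold_auroc))

    @property
    def sd_aupr(self) -> float:
        return float(np.std(self.fold_aupr, ddof=1)) if len(self.fold_aupr) > 1 else 0.0

    @property
    def sd_auroc(self) -> float:
        return float(np.std(self.fold_auroc, ddof=1)) if len(self.fold_auroc) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "fold_aupr": self.fold_aupr,
            "fold_auroc": self.fold_auroc,
            "mean_aupr": self.mean_aupr,
            "mean_auroc": self.mean_auroc,
            "sd_aupr": self.sd_aupr,
            "sd_auroc": self.sd_auroc,
            "config": self.config,
        }


def sample_negatives(Y: np.ndarray, ratio: float, seed: int) -> PairSample:
    """All positives plus ``ratio`` x as many uniformly sampled zero pairs.

    Sampling is without replacement and deterministic per seed. When fewer
    zero pairs exist than requested, all of them are taken and a warning is
    issued.
    """
    if ratio < 1:
        raise ValueError(f"negative sampling ratio must be >= 1, got {ratio}")
    Y = np.asarray(Y)
    pos = list(zip(*np.nonzero(Y)))
    zeros = list(zip(*np.nonzero(Y == 0)))
    n_neg = int(round(ratio * len(pos)))
    rng = np.random.default_rng(seed)
    if n_neg >= len(zeros):
        warnings.warn(
            f"requested {n_neg} negatives but only {len(zeros)} zero pairs exist; taking all"
        )
        neg = zeros
    else:
        idx = rng.choice(len(zeros), size=n_neg, replace=False)
        neg = [zeros[i] for i in idx]
    pairs = [(int(i), int(j), 1) for i, j in pos] + [(int(i), int(j), 0) for i, j in neg]
    return PairSample(pairs=pairs, ratio=ratio, seed=seed)


def kfold_split(sample: PairSample, k: int, seed: int) -> FoldSplit:
    """Stratified-by-label shuffled partition into k folds, deterministic per seed."""
    if k < 2:
        raise ValueError(f"need k >= 2 folds, got {k}")
    if not sample.pairs:
        raise ValueError("empty pair sample")
    labels = np.array([y for _, _, y in sample.pairs])
    if (labels == 1).sum() < k:
        raise DataValidationError(
            f"cannot stratify {int((labels == 1).sum())} positives into {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [
        [sample.pairs[i] for i in test_idx]
        for _, test_idx in skf.split(np.zeros(len(labels)), labels)
    ]
    return FoldSplit(folds=folds, seed=seed)


def ranking_metrics(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, float]:
    """(AUROC, AUPR) of a scored binary sample.

    AUROC is the Mann-Whitney statistic (probability a random positive
    outscores a random negative, ties half credit); AUPR is the
    non-interpolated step integral of precision over recall.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.min() == labels.max():
        raise DataValidationError("ranking metrics undefined for single-class labels")
    return float(roc_auc_score(labels, scores)), float(average_precision_score(labels, scores))


def redundancy_filter(
    Y: np.ndarray,
    drug_similarities: Optional[Mapping[str, np.ndarray]] = None,
    protein_similarities: Optional[Mapping[str, np.ndarray]] = None,
    drug_threshold: float = DEFAULT_THRESHOLDS["drug"],
    protein_threshold: float = DEFAULT_THRESHOLDS["protein"],
) -> tuple[np.ndarray, list[dict]]:
    """Remove drug-target associations that are redundant with a retained one.

    Positives are visited in lexicographic (drug, protein) order; a positive
    is removed when some already-kept positive shares its protein and the two
    drugs exceed ``drug_threshold`` in ANY supplied drug similarity, or
    shares its drug and the two proteins exceed ``protein_threshold`` in any
    supplied protein similarity. Which similarity maps are supplied selects
    the filtering mode (chemical-structure only, disease-Jaccard only,
    side-effect-Jaccard only, drugs-or-proteins, ...). Returns the reduced
    label matrix and a removal log.
    """
    drug_similarities = dict(drug_similarities or {})
    protein_similarities = dict(protein_similarities or {})
    if not drug_similarities and not protein_similarities:
        raise ConfigurationError("redundancy_filter needs at least one similarity matrix")
    Y = np.asarray(Y, dtype=float).copy()
    positives = sorted(zip(*np.nonzero(Y)))
    kept: list[tuple[int, int]] = []
    log: list[dict] = []
    for i, j in positives:
        reason = None
        for i2, j2 in kept:
            if j2 == j and i2 != i:
                for name, S in drug_similarities.items():
                    if S[i, i2] > drug_threshold:
                        reason = {"pair": (int(i), int(j)), "kept": (int(i2), int(j2)),
                                  "similarity": name, "value": float(S[i, i2])}
                        break
            elif i2 == i and j2 != j:
                for name, S in protein_similarities.items():
                    if S[j, j2] > protein_threshold:
                        reason = {"pair": (int(i), int(j)), "kept": (int(i2), int(j2)),
                                  "similarity": name, "value": float(S[j, j2])}
                        break
            if reason:
                break
        if reason:
            Y[i, j] = 0.0
            log.append(reason)
        else:
            kept.append((int(i), int(j)))
    return Y, log


def _pairs_to_mask(shape: tuple[int, int], test_pairs: Sequence[tuple[int, int, int]],
                   train_pairs: Optional[Sequence[tuple[int, int, int]]],
                   negatives: str) -> TrainMask:
    if negatives == "all":
        M = np.ones(shape)
        for i, j, _ in test_pairs:
            M[i, j] = 0.0
    elif negatives == "sampled":
        M = np.zeros(shape)
        for i, j, _ in train_pairs or []:
            M[i, j] = 1.0
    else:
        raise ConfigurationError(f"unknown negatives mode {negatives!r} (expected all|sampled)")
    for i, j, _ in test_pairs:
        assert M[i, j] == 0.0, "held-out pair leaked into the training mask"
    return TrainMask(M)


def cross_validate(
    hs: HeterogeneousNetworkSet,
    folds: int = 10,
    ratio: float = 10,
    seed: int = 7,
    drug_networks: Optional[Sequence[str]] = None,
    protein_networks: Optional[Sequence[str]] = None,
    homogeneous_mode: str = "jaccard",
    restart_prob: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 1000,
    d_drug: int = DEFAULT_D_DRUG,
    d_protein: int = DEFAULT_D_PROTEIN,
    pseudocount: Optional[float] = None,
    diffusion_backend: str = "iterative",
    adjacency_mode: str = "mean",
    negatives: str = "all",
    train_config: Optional[TrainConfig] = None,
) -> EvalReport:
    """k-fold cross-validated AUPR/AUROC of the full pipeline.

    Per fold, the held-out pairs (positives and sampled negatives) are
    removed from the supervision: test positives are zeroed in the training
    label matrix and all test pairs are masked out of the loss. The model is
    retrained from the same seed per fold and the held-out pairs are scored
    by the fitted decoder.
    """
    hs.validate()
    Y = hs.label_matrix
    sample = sample_negatives(Y, ratio=ratio, seed=seed)
    split = kfold_split(sample, k=folds, seed=seed)

    inventory = build_inventory(hs, drug_networks, protein_networks, homogeneous_mode)
    emb_drug = embed_node_type(inventory.drug, d=d_drug, p=restart_prob, tol=tol,
                               max_iter=max_iter, pseudocount=pseudocount,
                               backend=diffusion_backend)
    emb_protein = embed_node_type(inventory.protein, d=d_protein, p=restart_prob, tol=tol,
                                  max_iter=max_iter, pseudocount=pseudocount,
                                  backend=diffusion_backend)
    cfg = train_config or TrainConfig()
    adj_drug = build_gcn_adjacency(inventory, "drug", adjacency_mode) if cfg.gcn_enabled else None
    adj_protein = (
        build_gcn_adjacency(inventory, "protein", adjacency_mode) if cfg.gcn_enabled else None
    )

    fold_aupr: list[float] = []
    fold_auroc: list[float] = []
    for f, test_pairs in enumerate(split.folds):
        train_pairs = [p for g, fold in enumerate(split.folds) if g != f for p in fold]
        Y_train = Y.copy()
        for i, j, y in test_pairs:
            if y == 1:
                Y_train[i, j] = 0.0
        mask = _pairs_to_mask(Y.shape, test_pairs, train_pairs, negatives)
        _, scores, _ = train(Y_train, emb_drug.features, emb_protein.features,
                             adj_drug, adj_protein, mask=mask, config=cfg)
        test_scores = [scores.matrix[i, j] for i, j, _ in test_pairs]
        test_labels = [y for _, _, y in test_pairs]
        auroc, aupr = ranking_metrics(test_scores, test_labels)
        fold_auroc.append(auroc)
        fold_aupr.append(aupr)
        logger.info("fold %d/%d: AUROC=%.4f AUPR=%.4f", f + 1, folds, auroc, aupr)

    snapshot = {
        "folds": folds, "ratio": ratio, "seed": seed,
        "drug_networks": list(drug_networks) if drug_networks else None,
        "protein_networks": list(protein_networks) if protein_networks else None,
        "homogeneous_mode": homogeneous_mode, "restart_prob": restart_prob,
        "d_drug": d_drug, "d_protein": d_protein, "adjacency_mode": adjacency_mode,
        "negatives": negatives,
        "train": {"lr": cfg.lr, "epochs": cfg.epochs, "k": cfg.k,
                  "optimizer": cfg.optimizer, "seed": cfg.seed,
                  "gcn_enabled": cfg.gcn_enabled, "activation": cfg.activation},
    }
    return EvalReport(fold_aupr=fold_aupr, fold_auroc=fold_auroc, config=snapshot)
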