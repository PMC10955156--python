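"""End-to-end orchestration: load or simulate data, embed, train, score, evaluate, sweep.

The pipeline order is: similarity inventory -> per-network RWR diffusion ->
shared SVD embedding per node type -> one graph-convolution layer per node
type -> bilinear decoding of the drug-target matrix, trained by gradient
descent on the squared reconstruction error. Evaluation mode wraps the same
stages in seeded, stratified k-fold cross-validation.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd

from . import hetnet_io
from .config import load_config, set_path, snapshot
from .embedding import embed_node_type, write_embedding
from .evaluation import EvalReport, cross_validate, sample_negatives
from .exceptions import ConfigurationError
from .feature_update import build_gcn_adjacency
from .hetnet_io import (
    ASSOCIATION_SCHEMA,
    INTRA_TYPE_SCHEMA,
    PRECOMPUTED_SCHEMA,
    HeterogeneousNetworkSet,
    NodeRegistry,
    assemble,
    read_edge_list,
    read_similarity_matrix,
    write_score_matrix,
)
from .reconstruction import TrainConfig, TrainMask, train
from .similarity import build_inventory
from .synthetic import DEFAULT_DENSITIES, SyntheticConfig, generate

logger = logging.getLogger(__name__)


def load_network_set(cfg: dict) -> HeterogeneousNetworkSet:
    """Materialize the network set from the simulate block or from files."""
    paths = cfg["data"]["paths"]
    if paths is not None:
        return _read_from_paths(paths)
    sim = dict(cfg["data"]["simulate"])
    densities = {k: sim.pop(k) for k in list(sim) if k in DEFAULT_DENSITIES}
    scfg = SyntheticConfig(seed=cfg["seed"], **sim)
    if densities:
        scfg.densities.update(densities)
    return generate(scfg).network_set


def _read_from_paths(paths: Mapping[str, str]) -> HeterogeneousNetworkSet:
    registries: dict[str, NodeRegistry] = {}
    for nt in ("drug", "protein", "disease", "side_effect"):
        key = f"{nt}_nodes"
        registries[nt] = (
            NodeRegistry.from_file(paths[key], nt) if key in paths else NodeRegistry(nt)
        )
    associations = {}
    for name, (rt, ct) in ASSOCIATION_SCHEMA.items():
        if name not in paths:
            raise ConfigurationError(f"data.paths is missing {name!r}")
        associations[name] = read_edge_list(paths[name], registries[rt], registries[ct])
    intra = {}
    for name, nt in INTRA_TYPE_SCHEMA.items():
        if name not in paths:
            raise ConfigurationError(f"data.paths is missing {name!r}")
        intra[name] = read_edge_list(paths[name], registries[nt], registries[nt])
    precomputed = {}
    for name, nt in PRECOMPUTED_SCHEMA.items():
        if name not in paths:
            raise ConfigurationError(f"data.paths is missing {name!r}")
        precomputed[name] = read_similarity_matrix(paths[name], registries[nt], name=name)
    return assemble(registries, associations, intra, precomputed, drop_isolated=True)


def _embed_both(hs, cfg):
    inv = build_inventory(hs, cfg["networks"]["drug"], cfg["networks"]["protein"],
                          cfg["networks"]["homogeneous_mode"])
    dif = cfg["diffusion"]
    emb = cfg["embedding"]
    t0 = time.perf_counter()
    emb_drug = embed_node_type(inv.drug, d=emb["d_drug"], p=dif["restart_prob"],
                               pseudocount=emb["pseudocount"], tol=dif["tol"],
                               max_iter=dif["max_iter"], backend=dif["backend"])
    emb_protein = embed_node_type(inv.protein, d=emb["d_protein"], p=dif["restart_prob"],
                                  pseudocount=emb["pseudocount"], tol=dif["tol"],
                                  max_iter=dif["max_iter"], backend=dif["backend"])
    logger.info("embedding: drug %s, protein %s (%.2fs)", emb_drug.features.shape,
                emb_protein.features.shape, time.perf_counter() - t0)
    return inv, emb_drug, emb_protein


def _train_config(cfg: dict) -> TrainConfig:
    t = cfg["train"]
    return TrainConfig(lr=t["lr"], epochs=t["epochs"], k=t["k"], optimizer=t["optimizer"],
                       seed=cfg["seed"], gcn_enabled=cfg["gcn"]["enabled"],
                       activation=cfg["gcn"]["activation"], weight_decay=t["weight_decay"])


def run_pipeline(cfg: dict, mode: str = "predict") -> dict[str, Any]:
    """Execute the pipeline and write outputs to ``cfg['output_dir']``.

    ``mode='predict'`` trains on the full label matrix and writes the ranked
    score list; ``mode='evaluate'`` runs cross-validation and writes the
    metric report. Returns a summary dict (also written as JSON).
    """
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    snapshot(cfg, out_dir)
    hs = load_network_set(cfg)
    hs.validate()
    logger.info("network set: %d drugs, %d proteins", hs.n_drugs, hs.n_proteins)

    if mode == "evaluate":
        report = evaluate(cfg, hs)
        result: dict[str, Any] = report.to_dict()
        (out_dir / "eval_report.json").write_text(json.dumps(result, indent=2))
        pd.DataFrame({"fold": range(1, len(report.fold_aupr) + 1),
                      "aupr": report.fold_aupr,
                      "auroc": report.fold_auroc}).to_csv(out_dir / "fold_metrics.csv",
                                                          index=False)
        return result
    if mode != "predict":
        raise ConfigurationError(f"unknown pipeline mode {mode!r}")

    inv, emb_drug, emb_protein = _embed_both(hs, cfg)
    tcfg = _train_config(cfg)
    adj_d = build_gcn_adjacency(inv, "drug", cfg["gcn"]["adjacency_mode"]) if tcfg.gcn_enabled else None
    adj_p = build_gcn_adjacency(inv, "protein", cfg["gcn"]["adjacency_mode"]) if tcfg.gcn_enabled else None
    Y = hs.label_matrix
    t0 = time.perf_counter()
    model, scores, trace = train(Y, emb_drug.features, emb_protein.features,
                                 adj_d, adj_p, config=tcfg)
    logger.info("training: %d epochs, final loss %.6g (%.2fs)", tcfg.epochs, trace[-1],
                time.perf_counter() - t0)
    write_embedding(emb_drug, hs.registries["drug"].ids, out_dir / "drug_embedding.tsv")
    write_embedding(emb_protein, hs.registries["protein"].ids, out_dir / "protein_embedding.tsv")
    pd.DataFrame({"epoch": range(len(trace)), "loss": trace}).to_csv(
        out_dir / "loss_trace.csv", index=False)
    write_score_matrix(scores, hs.registries["drug"], hs.registries["protein"],
                       out_dir / "scores.tsv", top_k=cfg["output"]["top_k"],
                       exclude_mask=Y)
    result = {"final_loss": trace[-1], "epochs": tcfg.epochs,
              "n_drugs": hs.n_drugs, "n_proteins": hs.n_proteins,
              "score_matrix": str(out_dir / "scores.tsv")}
    (out_dir / "run_summary.json").write_text(json.dumps(result, indent=2))
    return result


def evaluate(cfg: dict, hs: Optional[HeterogeneousNetworkSet] = None) -> EvalReport:
    """Cross-validate the configured pipeline (library entry point)."""
    if hs is None:
        hs = load_network_set(cfg)
    return cross_validate(
        hs,
        folds=cfg["cv"]["folds"],
        ratio=cfg["cv"]["ratio"],
        seed=cfg["seed"],
        drug_networks=cfg["networks"]["drug"],
        protein_networks=cfg["networks"]["protein"],
        homogeneous_mode=cfg["networks"]["homogeneous_mode"],
        restart_prob=cfg["diffusion"]["restart_prob"],
        tol=cfg["diffusion"]["tol"],
        max_iter=cfg["diffusion"]["max_iter"],
        d_drug=cfg["embedding"]["d_drug"],
        d_protein=cfg["embedding"]["d_protein"],
        pseudocount=cfg["embedding"]["pseudocount"],
        diffusion_backend=cfg["diffusion"]["backend"],
        adjacency_mode=cfg["gcn"]["adjacency_mode"],
        negatives=cfg["train"]["negatives"],
        train_config=_train_config(cfg),
    )


def sweep(cfg: dict, grid: Mapping[str, list]) -> pd.DataFrame:
    """Cartesian-product cross-validation sweep over dot-path config keys.

    All cells share the base seed, so metric differences are attributable to
    the swept parameters. Every grid key is validated before any run starts.
    Returns one tidy row per cell with the swept values and the CV metrics.
    """
    keys = list(grid)
    for key in keys:  # fail fast on typos
        set_path(cfg, key, grid[key][0])
    rows = []
    hs = load_network_set(cfg)
    for values in itertools.product(*(grid[k] for k in keys)):
        cell = cfg
        for key, val in zip(keys, values):
            cell = set_path(cell, key, val)
        report = evaluate(cell, hs)
        row = dict(zip(keys, values))
        row.update(mean_aupr=report.mean_aupr, mean_auroc=report.mean_auroc,
                   sd_aupr=report.sd_aupr, sd_auroc=report.sd_auroc)
        rows.append(row)
        logger.info("sweep %s -> AUROC %.4f AUPR %.4f",
                    dict(zip(keys, values)), report.mean_auroc, report.mean_aupr)
    return pd.DataFrame(rows)


def simulate_to_dir(cfg: dict, out_dir: str | Path) -> Path:
    """Write the synthetic network set as edge lists / TSV tables plus ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dict(cfg["data"]["simulate"])
    densities = {k: sim.pop(k) for k in list(sim) if k in DEFAULT_DENSITIES}
    scfg = SyntheticConfig(seed=cfg["seed"], **sim)
    if densities:
        scfg.densities.update(densities)
    ds = generate(scfg)
    hs = ds.network_set
    for nt, reg in hs.registries.items():
        reg.to_file(out / f"{nt}_nodes.txt")
    for name, assoc in hs.associations.items():
        rt, ct = ASSOCIATION_SCHEMA[name]
        hetnet_io.write_edge_list(assoc, hs.registries[rt], hs.registries[ct],
                                  out / f"{name}.tsv")
    for name, assoc in hs.intra_type.items():
        nt = INTRA_TYPE_SCHEMA[name]
        hetnet_io.write_edge_list(assoc, hs.registries[nt], hs.registries[nt],
                                  out / f"{name}.tsv")
    for name, sim_m in hs.precomputed.items():
        nt = PRECOMPUTED_SCHEMA[name]
        hetnet_io.write_similarity_matrix(sim_m, hs.registries[nt], out / f"{name}.tsv")
    np.savetxt(out / "ground_truth_labels.tsv", ds.noiseless_labels, fmt="%d", delimiter="\t")
    return out
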