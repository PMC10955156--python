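"""Run configuration: nested defaults, YAML loading, dot-path overrides.

Every key has a documented default; unknown keys are rejected up front so a
typo cannot silently fall back to a default. A verbatim snapshot of the
merged configuration is written into every output directory.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from .exceptions import ConfigurationError

DEFAULTS: dict[str, Any] = {
    "seed": 7,
    "output_dir": "results",
    "data": {
        # either a simulate block (synthetic generator) or file paths
        "simulate": {
            "n_drugs": 50,
            "n_proteins": 80,
            "n_diseases": 30,
            "n_side_effects": 20,
            "latent_rank": 3,
            "label_noise": 0.0,
            "similarity_noise": 0.05,
            "planted": True,
        },
        "paths": None,  # mapping of network name -> file, see hetnet_io schemas
    },
    "networks": {
        "drug": None,       # None -> the full default inventory
        "protein": None,
        "homogeneous_mode": "jaccard",  # jaccard | adjacency
    },
    "diffusion": {
        "restart_prob": 0.5,
        "tol": 1.0e-8,
        "max_iter": 1000,
        "backend": "iterative",  # iterative | closed_form
    },
    "embedding": {
        "d_drug": 200,
        "d_protein": 400,
        "pseudocount": None,  # None -> 1/n
    },
    "gcn": {
        "enabled": True,
        "activation": "relu",
        "adjacency_mode": "mean",  # mean | primary
    },
    "train": {
        "lr": 0.01,
        "epochs": 500,
        "k": None,             # decoder width; None -> min(d_drug, d_protein)
        "optimizer": "adam",   # adam | gd
        "negatives": "all",    # all | sampled
        "weight_decay": 0.0,
    },
    "cv": {
        "folds": 10,
        "ratio": 10,
    },
    "output": {
        "top_k": None,
    },
}


def _merge(base: dict, override: Mapping, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        full = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigurationError(f"unknown config key {full!r}")
        if isinstance(base[key], dict) and base[key] and isinstance(val, Mapping):
            out[key] = _merge(base[key], val, full)
        else:
            out[key] = copy.deepcopy(val) if isinstance(val, (dict, list)) else val
    return out


def load_config(path: Optional[str | Path] = None,
                overrides: Optional[Mapping[str, Any]] = None) -> dict:
    """Merge DEFAULTS <- YAML file <- dot-path overrides, rejecting unknown keys."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, Mapping):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        cfg = _merge(cfg, doc)
    for dotted, value in (overrides or {}).items():
        cfg = set_path(cfg, dotted, value)
    return cfg


def set_path(cfg: dict, dotted: str, value: Any) -> dict:
    """Return a copy of cfg with the dot-separated key set; key must exist."""
    parts = dotted.split(".")
    out = copy.deepcopy(cfg)
    node = out
    for i, part in enumerate(parts):
        if not isinstance(node, dict) or part not in node:
            raise ConfigurationError(f"unknown config key {dotted!r}")
        if i == len(parts) - 1:
            node[part] = value
        else:
            node = node[part]
    return out


def snapshot(cfg: dict, out_dir: str | Path) -> Path:
    """Write the merged config verbatim into the output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "config.yaml"
    path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return path
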