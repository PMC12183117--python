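"""Run configuration: YAML files, defaults, overrides, schema validation.

Precedence is CLI flag > config file > built-in default.  Unknown keys are
rejected before any work starts.
"""

from __future__ import annotations

import copy
import hashlib
import json

import yaml

from .errors import ValidationError

#: the full configuration schema with built-in defaults
DEFAULTS: dict = {
    "seed": 0,
    "namespace": "BP",
    "data": {
        "obo": None,
        "annotations": None,
        "embeddings": None,
        "links": None,
        "id_map": None,
        "score_scale": "auto",
    },
    "model": {
        "type": "mlp",            # mlp | gnn
        "hidden_dims": [128],
        "dropout": 0.3,
        "min_count": 1,
    },
    "loss": {
        "alpha": 0.1,
        "temperature": 0.5,
    },
    "graph": {
        "architecture": "GAT",    # GAT | GCN | GIN
        "layers": 2,
        "heads": 4,
        "hidden_dim": 64,
        "k": 100,
        "min_conf": None,
    },
    "train": {
        "max_epochs": 50,
        "batch_size": 64,
        "learning_rate": 1e-3,
        "patience": 10,
        "metric": "fmax",
        "split": [0.8, 0.2],
    },
    "eval": {
        "step": 0.01,
        "aupr_mode": "term-centric",
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ValidationError(f"unknown config key: {here}")
        if isinstance(base[key], dict) and base[key]:
            if not isinstance(value, dict):
                raise ValidationError(f"config key {here} must be a mapping")
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merged configuration: defaults <- YAML file <- overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as f:
            file_cfg = yaml.safe_load(f) or {}
        if not isinstance(file_cfg, dict):
            raise ValidationError("config file must be a YAML mapping")
        cfg = _merge(cfg, file_cfg)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    """Short stable digest of a configuration, for run logging."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
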