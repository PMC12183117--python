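"""Model checkpoints: a JSON config block plus named parameter arrays.

A checkpoint is a single ``.npz`` container holding every parameter array
under its name, plus a ``__config__`` entry with the JSON-serialized model
spec, so a trained model can be reloaded without the original code path
that built it.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np

from .errors import ValidationError
from .models import GnnConfig, MlpHeadConfig
from .nn.autograd import Tensor


def save_checkpoint(path, spec, params: dict[str, Tensor], vocab: list[str]) -> None:
    spec_block = {"kind": type(spec).__name__, "config": asdict(spec), "vocab": vocab}
    arrays = {k: p.data for k, p in params.items()}
    np.savez(path, __config__=np.frombuffer(
        json.dumps(spec_block).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    """Returns (spec, params, vocab)."""
    with np.load(path) as data:
        if "__config__" not in data.files:
            raise ValidationError("not a checkpoint: missing __config__ block")
        block = json.loads(bytes(data["__config__"]).decode())
        params = {
            k: Tensor(data[k], requires_grad=True)
            for k in data.files
            if k != "__config__"
        }
    kind = block["kind"]
    if kind == "MlpHeadConfig":
        spec = MlpHeadConfig(**block["config"])
    elif kind == "GnnConfig":
        spec = GnnConfig(**block["config"])
    else:
        raise ValidationError(f"unknown model spec kind: {kind}")
    return spec, params, block["vocab"]
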