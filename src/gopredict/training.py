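"""Seeded training of the modality models, prediction, and ensembling.

Each modality model (sequence MLP, structure-aware MLP, ego-graph GNN) is
trained independently on the combined BCE + contrastive objective, with
early stopping on a validation metric (Fmax by default).  Prediction
applies the logistic transform to the logits; the ensemble is the
equal-weight elementwise mean of the three probability matrices.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .containers import ScoreMatrix
from .errors import ValidationError
from .evaluation import fmax_arrays
from .losses import LossConfig, bce_loss, combined_loss
from .models import (
    GnnConfig,
    LabelEmbedderConfig,
    MlpHeadConfig,
    embed_labels,
    gnn_forward,
    init_gnn_params,
    init_label_embedder_params,
    init_mlp_params,
    mlp_forward,
)
from .nn import Adam
from .nn.autograd import Tensor, _stable_sigmoid
from .seeds import substream


@dataclass
class TrainConfig:
    max_epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    early_stopping_patience: int = 10
    early_stopping_metric: str = "fmax"  # or "loss"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.early_stopping_patience < 1:
            raise ValidationError("patience must be >= 1")
        if self.early_stopping_metric not in {"fmax", "loss"}:
            raise ValidationError(
                f"unknown early-stopping metric: {self.early_stopping_metric!r}"
            )


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_fmax: list[float] = field(default_factory=list)
    best_epoch: int = 0

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def _forward(spec, params, inputs, train: bool, rng=None) -> Tensor:
    if isinstance(spec, MlpHeadConfig):
        return mlp_forward(spec, params, inputs, train=train, rng=rng)
    if isinstance(spec, GnnConfig):
        return gnn_forward(spec, params, inputs, train=train, rng=rng)
    raise TypeError(f"unknown model spec type: {type(spec).__name__}")


def _take(inputs, idx):
    if isinstance(inputs, np.ndarray):
        return inputs[idx]
    return [inputs[i] for i in idx]


def _init_params(spec, rng):
    if isinstance(spec, MlpHeadConfig):
        return init_mlp_params(spec, rng)
    return init_gnn_params(spec, rng)


def train_model(
    train_data,
    val_data,
    model_spec,
    loss_config: LossConfig | None = None,
    train_config: TrainConfig | None = None,
):
    """Train one modality model; returns (best parameters, history).

    *train_data* / *val_data* are (inputs, labels) pairs: inputs an
    n x d embedding matrix for an :class:`MlpHeadConfig` spec or a list of
    featured ego-graphs for a :class:`GnnConfig` spec; labels an n x T
    binary matrix over one shared term vocabulary (ancestor-propagated).
    Parameters from the best validation epoch are returned; training stops
    once the monitored metric fails to improve for ``patience`` epochs.
    Fully reproducible given ``train_config.seed``.
    """
    loss_config = loss_config or LossConfig()
    cfg = train_config or TrainConfig()
    X_train, Y_train = train_data
    X_val, Y_val = val_data
    Y_train = np.asarray(Y_train, dtype=np.float64)
    Y_val = np.asarray(Y_val, dtype=np.float64)
    n = Y_train.shape[0]
    if n == 0:
        raise ValidationError("empty training set")
    if Y_train.shape[1] != Y_val.shape[1]:
        raise ValidationError(
            f"train/val vocabulary mismatch: {Y_train.shape[1]} vs {Y_val.shape[1]}"
        )
    if Y_train.shape[1] != model_spec.output_dim:
        raise ValidationError(
            f"label width {Y_train.shape[1]} != model output_dim "
            f"{model_spec.output_dim}"
        )
    contrastive = loss_config.training_mode and loss_config.alpha > 0.0
    if contrastive and cfg.batch_size < 2:
        raise ValidationError("batch_size must be >= 2 when the contrastive "
                              "term is active (it needs in-batch negatives)")

    init_rng = substream(cfg.seed, "init")
    shuffle_rng = substream(cfg.seed, "shuffle")
    dropout_rng = substream(cfg.seed, "dropout")

    params = _init_params(model_spec, init_rng)
    embedder_cfg = None
    embedder_params: dict[str, Tensor] = {}
    if contrastive:
        embedder_cfg = LabelEmbedderConfig(
            num_labels=model_spec.output_dim, output_dim=model_spec.output_dim
        )
        embedder_params = init_label_embedder_params(embedder_cfg, init_rng)

    all_params = dict(params)
    all_params.update({f"labemb_{k}": v for k, v in embedder_params.items()})
    opt = Adam(all_params, learning_rate=cfg.learning_rate)

    def embedder(labels):
        return embed_labels(embedder_cfg, embedder_params, labels)

    history = TrainHistory()
    best_metric = None
    best_params = None
    best_epoch = 0
    stall = 0
    maximize = cfg.early_stopping_metric == "fmax"

    for epoch in range(cfg.max_epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if contrastive and len(idx) < 2:
                continue  # a singleton batch has no negatives
            logits = _forward(
                model_spec, params, _take(X_train, idx), train=True, rng=dropout_rng
            )
            loss = combined_loss(
                logits,
                Y_train[idx],
                label_embedder=embedder if contrastive else None,
                loss_config=loss_config,
            )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(idx)
        history.train_loss.append(epoch_loss / n)

        val_logits = _forward(model_spec, params, X_val, train=False)
        history.val_loss.append(bce_loss(val_logits, Y_val).item())
        val_probs = _stable_sigmoid(val_logits.data)
        history.val_fmax.append(fmax_arrays(val_probs, Y_val > 0.5).fmax)

        metric = history.val_fmax[-1] if maximize else history.val_loss[-1]
        improved = (
            best_metric is None
            or (maximize and metric > best_metric)
            or (not maximize and metric < best_metric)
        )
        if improved:
            best_metric = metric
            best_epoch = epoch
            best_params = {
                k: copy.deepcopy(v.data) for k, v in all_params.items()
            }
            stall = 0
        else:
            stall += 1
            if stall >= cfg.early_stopping_patience:
                break

    history.best_epoch = best_epoch
    for k, v in all_params.items():
        v.data = best_params[k]
    return params, history


def predict(
    params,
    model_spec,
    inputs,
    protein_ids: list[str],
    term_ids: list[str],
) -> ScoreMatrix:
    """Score proteins: logistic transform of the eval-mode logits.

    No label information and no dropout are used; repeated calls are
    identical.
    """
    logits = _forward(model_spec, params, inputs, train=False)
    probs = _stable_sigmoid(logits.data)
    if probs.shape != (len(protein_ids), len(term_ids)):
        raise ValidationError(
            f"prediction shape {probs.shape} does not match "
            f"{len(protein_ids)} proteins x {len(term_ids)} terms"
        )
    return ScoreMatrix(list(protein_ids), list(term_ids), probs)


def ensemble_average(matrices: list[ScoreMatrix]) -> ScoreMatrix:
    """Equal-weight elementwise mean of probability matrices.

    All matrices must cover identical protein and term id sets (order may
    differ; later matrices are reindexed to the first)."""
    if not matrices:
        raise ValidationError("ensemble_average needs at least one matrix")
    ref = matrices[0]
    ref_p, ref_t = set(ref.proteins), set(ref.terms)
    # mean computed as ref + mean(deviations): identical inputs average to
    # the input bit-exactly
    dev = np.zeros_like(ref.values)
    for m in matrices[1:]:
        if set(m.terms) != ref_t:
            diff = sorted(set(m.terms) ^ ref_t)
            raise ValidationError(f"term vocabularies differ: {diff}")
        if set(m.proteins) != ref_p:
            diff = sorted(set(m.proteins) ^ ref_p)
            raise ValidationError(f"protein id sets differ: {diff}")
        dev += m.reindex(ref.proteins, ref.terms).values - ref.values
    values = np.clip(ref.values + dev / len(matrices), 0.0, 1.0)
    return ScoreMatrix(list(ref.proteins), list(ref.terms), values)
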