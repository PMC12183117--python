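"""The three predictor architectures and the label-embedding network.

* an MLP head over fixed protein embeddings (sequence or structure-aware
  modality): blocks of linear -> SiLU -> dropout, final linear to one
  logit per GO term;
* a message-passing network over PPI ego-graphs (GAT with multi-head
  attention, GCN with symmetric degree normalization, or GIN with
  sum-aggregation + MLP), read out at the query (center) node;
* a two-linear-layer label embedder mapping a protein's multi-hot GO
  label vector into the predictor's output space, used only by the
  contrastive term during training.

All forward functions return logits (no output nonlinearity); dropout is
active only in training mode and is driven by an explicit RNG so runs are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .graphs import EgoGraph
from .nn import autograd as ag
from .nn.autograd import Tensor


# --------------------------------------------------------------------------
# configs


@dataclass
class MlpHeadConfig:
    input_dim: int
    output_dim: int
    hidden_dims: list[int] = field(default_factory=lambda: [256])
    dropout_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.output_dim < 1:
            raise ValidationError("output_dim must be >= 1")
        if not self.hidden_dims:
            raise ValidationError("hidden_dims must be non-empty")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValidationError("dropout_rate must be in [0, 1)")


@dataclass
class GnnConfig:
    input_dim: int
    output_dim: int
    architecture: str = "GAT"
    num_layers: int = 2
    hidden_dim: int = 256
    attention_heads: int = 4
    dropout_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.architecture not in {"GAT", "GCN", "GIN"}:
            raise ValidationError(f"unknown architecture: {self.architecture!r}")
        if self.num_layers < 1:
            raise ValidationError("num_layers must be >= 1")
        if self.architecture == "GAT":
            if self.attention_heads < 1:
                raise ValidationError("attention_heads must be >= 1")
            if self.hidden_dim % self.attention_heads != 0:
                raise ValidationError(
                    "hidden_dim must be divisible by attention_heads"
                )


@dataclass
class LabelEmbedderConfig:
    num_labels: int
    output_dim: int
    hidden_dim: int = 128


# --------------------------------------------------------------------------
# parameter initialization


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=(fan_in, fan_out)),
                  requires_grad=True)


def _zeros(n: int) -> Tensor:
    return Tensor(np.zeros(n), requires_grad=True)


def init_mlp_params(config: MlpHeadConfig, rng: np.random.Generator):
    params: dict[str, Tensor] = {}
    dims = [config.input_dim] + list(config.hidden_dims) + [config.output_dim]
    for i, (d_in, d_out) in enumerate(zip(dims[:-1], dims[1:])):
        params[f"W{i}"] = _glorot(rng, d_in, d_out)
        params[f"b{i}"] = _zeros(d_out)
    return params


def init_label_embedder_params(config: LabelEmbedderConfig, rng: np.random.Generator):
    return {
        "W0": _glorot(rng, config.num_labels, config.hidden_dim),
        "b0": _zeros(config.hidden_dim),
        "W1": _glorot(rng, config.hidden_dim, config.output_dim),
        "b1": _zeros(config.output_dim),
    }


def init_gnn_params(config: GnnConfig, rng: np.random.Generator):
    params: dict[str, Tensor] = {}
    d_in = config.input_dim
    for layer in range(config.num_layers):
        d_out = config.hidden_dim
        if config.architecture == "GAT":
            per_head = d_out // config.attention_heads
            for h in range(config.attention_heads):
                params[f"L{layer}_W{h}"] = _glorot(rng, d_in, per_head)
                params[f"L{layer}_asrc{h}"] = _glorot(rng, per_head, 1)
                params[f"L{layer}_adst{h}"] = _glorot(rng, per_head, 1)
            params[f"L{layer}_b"] = _zeros(d_out)
        elif config.architecture == "GCN":
            params[f"L{layer}_W"] = _glorot(rng, d_in, d_out)
            params[f"L{layer}_b"] = _zeros(d_out)
        else:  # GIN
            params[f"L{layer}_W0"] = _glorot(rng, d_in, d_out)
            params[f"L{layer}_b0"] = _zeros(d_out)
            params[f"L{layer}_W1"] = _glorot(rng, d_out, d_out)
            params[f"L{layer}_b1"] = _zeros(d_out)
        d_in = d_out
    params["Wout"] = _glorot(rng, d_in, config.output_dim)
    params["bout"] = _zeros(config.output_dim)
    return params


# --------------------------------------------------------------------------
# forward passes


def mlp_forward(
    config: MlpHeadConfig,
    params: dict[str, Tensor],
    batch: np.ndarray,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Blocks of linear -> SiLU -> dropout, final linear to logits."""
    batch = np.asarray(batch, dtype=np.float64)
    if batch.ndim != 2 or batch.shape[1] != config.input_dim:
        raise ValidationError(
            f"batch shape {batch.shape} does not match input_dim {config.input_dim}"
        )
    if train and config.dropout_rate > 0 and rng is None:
        raise ValueError("training-mode dropout requires an rng")
    h = Tensor(batch)
    n_hidden = len(config.hidden_dims)
    for i in range(n_hidden):
        h = ag.silu(h @ params[f"W{i}"] + params[f"b{i}"])
        h = ag.dropout(h, config.dropout_rate, rng, train)
    return h @ params[f"W{n_hidden}"] + params[f"b{n_hidden}"]


def embed_labels(
    config: LabelEmbedderConfig, params: dict[str, Tensor], labels: np.ndarray
) -> Tensor:
    """linear -> SiLU -> linear on a binary N x num_labels matrix."""
    labels = np.asarray(labels, dtype=np.float64)
    if labels.ndim != 2 or labels.shape[1] != config.num_labels:
        raise ValidationError(
            f"labels shape {labels.shape} does not match num_labels "
            f"{config.num_labels}"
        )
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValidationError("label matrix must be binary")
    h = ag.silu(Tensor(labels) @ params["W0"] + params["b0"])
    return h @ params["W1"] + params["b1"]


def _batch_graphs(graphs: list[EgoGraph]):
    """Merge ego-graphs into one disjoint node set with offset edge indices."""
    feats, srcs, dsts, centers = [], [], [], []
    offset = 0
    dim = None
    for g in graphs:
        if g.features is None:
            raise ValidationError(f"graph for {g.center} has no node features")
        if dim is None:
            dim = g.features.shape[1]
        elif g.features.shape[1] != dim:
            raise ValidationError("graphs in a batch must share feature dim")
        src, dst, _ = g.directed_arcs()
        feats.append(g.features.astype(np.float64))
        srcs.append(src + offset)
        dsts.append(dst + offset)
        centers.append(offset)  # center is node 0 of each graph
        offset += g.num_nodes
    return (
        np.concatenate(feats),
        np.concatenate(srcs),
        np.concatenate(dsts),
        np.asarray(centers, dtype=np.int64),
        offset,
    )


def _gat_layer(params, layer, h, src, dst, n_nodes, heads):
    head_outs = []
    for head in range(heads):
        wh = h @ params[f"L{layer}_W{head}"]
        e_src = wh @ params[f"L{layer}_asrc{head}"]
        e_dst = wh @ params[f"L{layer}_adst{head}"]
        e = ag.leaky_relu(
            ag.gather_rows(e_src, src) + ag.gather_rows(e_dst, dst), 0.2
        )
        # per-destination softmax; subtracting the per-segment max is a
        # value-level shift the softmax is invariant to
        seg_max = np.full((n_nodes, 1), -np.inf)
        np.maximum.at(seg_max, dst, e.data)
        w = ag.exp(e - Tensor(seg_max[dst]))
        denom = ag.segment_sum(w, dst, n_nodes)
        coef = w / ag.gather_rows(denom, dst)
        msg = coef * ag.gather_rows(wh, src)
        head_outs.append(ag.segment_sum(msg, dst, n_nodes))
    out = head_outs[0] if len(head_outs) == 1 else ag.concat_columns(head_outs)
    return out + params[f"L{layer}_b"]


def _gcn_layer(params, layer, h, src, dst, n_nodes):
    deg = np.bincount(dst, minlength=n_nodes).astype(np.float64)
    coef = 1.0 / np.sqrt(deg[src] * deg[dst])
    wh = h @ params[f"L{layer}_W"]
    msg = Tensor(coef[:, None]) * ag.gather_rows(wh, src)
    return ag.segment_sum(msg, dst, n_nodes) + params[f"L{layer}_b"]


def _gin_layer(params, layer, h, src, dst, n_nodes):
    non_loop = src != dst
    agg = ag.segment_sum(ag.gather_rows(h, src[non_loop]), dst[non_loop], n_nodes)
    combined = h + agg  # epsilon fixed at 0
    hidden = ag.silu(combined @ params[f"L{layer}_W0"] + params[f"L{layer}_b0"])
    return hidden @ params[f"L{layer}_W1"] + params[f"L{layer}_b1"]


def gnn_forward(
    config: GnnConfig,
    params: dict[str, Tensor],
    graphs: list[EgoGraph],
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Message passing on a batch of featured ego-graphs; returns one
    logits row per graph, read out at its center node."""
    if not graphs:
        raise ValidationError("empty graph batch")
    if train and config.dropout_rate > 0 and rng is None:
        raise ValueError("training-mode dropout requires an rng")
    feats, src, dst, centers, n_nodes = _batch_graphs(graphs)
    if feats.shape[1] != config.input_dim:
        raise ValidationError(
            f"feature dim {feats.shape[1]} does not match input_dim "
            f"{config.input_dim}"
        )
    h = Tensor(feats)
    for layer in range(config.num_layers):
        if config.architecture == "GAT":
            h = _gat_layer(params, layer, h, src, dst, n_nodes,
                           config.attention_heads)
        elif config.architecture == "GCN":
            h = _gcn_layer(params, layer, h, src, dst, n_nodes)
        else:
            h = _gin_layer(params, layer, h, src, dst, n_nodes)
        h = ag.silu(h)
        h = ag.dropout(h, config.dropout_rate, rng, train)
    center_h = ag.gather_rows(h, centers)
    return center_h @ params["Wout"] + params["bout"]
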