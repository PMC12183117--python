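"""The dual-loss training objective: BCE plus a label-embedding InfoNCE term.

Each protein's predicted logit vector Z_i is treated as an anchor whose
positive is the embedding M_i of its own GO label vector; the label
embeddings of the other proteins in the mini-batch are its negatives.
With cosine similarity and temperature tau, the contrastive term is

    L = -(1/N) sum_i log[ exp(cos(Z_i, M_i)/tau) /
                          sum_j exp(cos(Z_i, M_j)/tau) ]

and the total training loss is BCE + alpha * L (alpha defaults to 0.1).
The contrastive term is used only during training; evaluation and
inference score with BCE-calibrated logits and no label input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .nn import autograd as ag
from .nn.autograd import Tensor


@dataclass
class LossConfig:
    """Weights and switches for the combined objective.

    alpha: weight of the contrastive term (0 disables it exactly).
    temperature: softmax temperature tau of the InfoNCE term.
    training_mode: when False the contrastive term is skipped entirely.
    symmetric: add the M-anchored direction as well (averaged).
    mask_duplicate_negatives: exclude in-batch proteins with an identical
        label vector from the negatives (they would be false negatives);
        off by default.
    """

    alpha: float = 0.1
    temperature: float = 0.5
    training_mode: bool = True
    symmetric: bool = False
    mask_duplicate_negatives: bool = False

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValidationError("alpha must be >= 0")
        if self.temperature <= 0:
            raise ValidationError("temperature must be > 0")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def bce_loss(logits, labels) -> Tensor:
    """Mean binary cross-entropy over all N x T logit/label entries."""
    logits = _as_tensor(logits)
    labels = np.asarray(labels, dtype=np.float64)
    return ag.bce_with_logits(logits, labels)


def info_nce_loss(
    Z,
    M,
    temperature: float,
    symmetric: bool = False,
    duplicate_mask: np.ndarray | None = None,
) -> Tensor:
    """InfoNCE over cosine similarities of protein outputs Z and label
    embeddings M (both N x D, row i of M the positive for row i of Z).

    Zero-norm rows have cosine similarity defined as 0.  *duplicate_mask*,
    when given, is an N x N boolean matrix marking (i, j) pairs to exclude
    from the negatives (the diagonal is never excluded).
    """
    Z, M = _as_tensor(Z), _as_tensor(M)
    if Z.shape != M.shape:
        raise ValidationError(f"Z shape {Z.shape} != M shape {M.shape}")
    if Z.data.ndim != 2 or Z.shape[0] < 1:
        raise ValidationError("Z and M must be N x D with N >= 1")
    if not (np.isfinite(Z.data).all() and np.isfinite(M.data).all()):
        raise ValidationError("non-finite entries in contrastive batch")
    if temperature <= 0:
        raise ValidationError("temperature must be > 0")

    sims = ag.matmul(ag.normalize_rows(Z), ag.transpose(ag.normalize_rows(M)))
    logits = sims * (1.0 / temperature)
    if duplicate_mask is not None:
        mask = np.asarray(duplicate_mask, dtype=bool).copy()
        np.fill_diagonal(mask, False)
        logits = logits + Tensor(np.where(mask, -1e30, 0.0))
    loss = ag.mean(ag.logsumexp(logits, axis=1) - ag.take_diag(logits))
    if symmetric:
        rev = ag.mean(
            ag.logsumexp(ag.transpose(logits), axis=1) - ag.take_diag(logits)
        )
        loss = (loss + rev) * 0.5
    return loss


def duplicate_label_mask(labels: np.ndarray) -> np.ndarray:
    """N x N boolean matrix: True where two rows have identical labels."""
    labels = np.asarray(labels)
    return (labels[:, None, :] == labels[None, :, :]).all(axis=2)


def combined_loss(
    logits,
    labels: np.ndarray,
    label_embedder=None,
    loss_config: LossConfig | None = None,
) -> Tensor:
    """BCE plus alpha-weighted InfoNCE between the logits and the embedded
    label vectors; reduces to BCE alone when alpha == 0 or outside
    training mode.

    *label_embedder* is a callable ``labels -> Tensor`` (e.g. a bound
    :func:`gopredict.models.embed_labels`); it is only invoked when the
    contrastive term is active.
    """
    cfg = loss_config or LossConfig()
    logits = _as_tensor(logits)
    labels = np.asarray(labels, dtype=np.float64)
    b = bce_loss(logits, labels)
    if not cfg.training_mode or cfg.alpha == 0.0:
        return b
    if label_embedder is None:
        raise ValueError("label_embedder required when the contrastive term is active")
    M = label_embedder(labels)
    mask = duplicate_label_mask(labels) if cfg.mask_duplicate_negatives else None
    c = info_nce_loss(
        logits, M, cfg.temperature, symmetric=cfg.symmetric, duplicate_mask=mask
    )
    return b + cfg.alpha * c
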