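"""Model / Results interface over the training core.

Following the fit-then-results convention of statistical modelling
packages, a model object is built from data (an embedding store or an
interaction table, plus propagated annotations and an id split) and its
:meth:`fit` returns a :class:`FunctionModelResults` carrying the trained
parameters, the training history, diagnostics and ``summary()``;
prediction and ensembling hang off the results object.

    >>> model = EmbeddingFunctionModel(store, annots, train_ids, val_ids)
    >>> res = model.fit(TrainConfig(seed=0))
    >>> scores = res.predict(test_ids)
    >>> print(res.summary())
"""

from __future__ import annotations

import numpy as np

from .containers import InteractionTable, ScoreMatrix
from .embeddings import EmbeddingStore
from .errors import ValidationError
from .graphs import attach_features, build_ego_graph
from .losses import LossConfig
from .models import GnnConfig, MlpHeadConfig
from .ontology import AnnotationSet
from .training import TrainConfig, TrainHistory, ensemble_average, predict, train_model

__all__ = [
    "build_vocabulary",
    "label_matrix",
    "EmbeddingFunctionModel",
    "GraphFunctionModel",
    "FunctionModelResults",
    "ensemble_average",
]


def build_vocabulary(annots: AnnotationSet, min_count: int = 1) -> list[str]:
    """Term vocabulary: terms in the (propagated) annotations with
    annotation count >= min_count, in sorted order."""
    counts: dict[str, int] = {}
    for terms in annots.annotations.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    vocab = sorted(t for t, c in counts.items() if c >= min_count)
    if not vocab:
        raise ValidationError("empty term vocabulary")
    return vocab


def label_matrix(
    annots: AnnotationSet, proteins: list[str], vocab: list[str]
) -> np.ndarray:
    """Binary n x T matrix of *proteins*' annotations over *vocab*."""
    index = {t: j for j, t in enumerate(vocab)}
    y = np.zeros((len(proteins), len(vocab)))
    for i, p in enumerate(proteins):
        for t in annots.annotations.get(p, ()):
            j = index.get(t)
            if j is not None:
                y[i, j] = 1.0
    return y


class _BaseFunctionModel:
    """Shared fit machinery; subclasses supply ``_inputs_for(ids)``."""

    def __init__(
        self,
        annots: AnnotationSet,
        train_ids: list[str],
        val_ids: list[str],
        vocab: list[str] | None,
        min_count: int,
        loss_config: LossConfig | None,
    ):
        self.annots = annots
        self.train_ids = list(train_ids)
        self.val_ids = list(val_ids)
        if vocab is None:
            train_annots = AnnotationSet(
                annotations={
                    p: annots.annotations.get(p, set()) for p in self.train_ids
                },
                namespace=annots.namespace,
            )
            vocab = build_vocabulary(train_annots, min_count=min_count)
        self.vocab = list(vocab)
        self.loss_config = loss_config or LossConfig()
        self.spec = None  # set by subclass

    def _inputs_for(self, ids: list[str]):
        raise NotImplementedError

    def fit(self, train_config: TrainConfig | None = None) -> "FunctionModelResults":
        cfg = train_config or TrainConfig()
        y_train = label_matrix(self.annots, self.train_ids, self.vocab)
        y_val = label_matrix(self.annots, self.val_ids, self.vocab)
        params, history = train_model(
            (self._inputs_for(self.train_ids), y_train),
            (self._inputs_for(self.val_ids), y_val),
            self.spec,
            loss_config=self.loss_config,
            train_config=cfg,
        )
        return FunctionModelResults(self, params, history, cfg)


class EmbeddingFunctionModel(_BaseFunctionModel):
    """MLP head over fixed per-protein embeddings (one modality)."""

    def __init__(
        self,
        store: EmbeddingStore,
        annots: AnnotationSet,
        train_ids: list[str],
        val_ids: list[str],
        vocab: list[str] | None = None,
        min_count: int = 1,
        hidden_dims: list[int] | None = None,
        dropout_rate: float = 0.3,
        loss_config: LossConfig | None = None,
    ):
        super().__init__(annots, train_ids, val_ids, vocab, min_count, loss_config)
        self.store = store
        self.spec = MlpHeadConfig(
            input_dim=store.dim,
            output_dim=len(self.vocab),
            hidden_dims=hidden_dims or [128],
            dropout_rate=dropout_rate,
        )

    def _inputs_for(self, ids: list[str]):
        return self.store.batch(ids)


class GraphFunctionModel(_BaseFunctionModel):
    """Message-passing network over per-query PPI ego-graphs."""

    def __init__(
        self,
        table: InteractionTable,
        feature_store: EmbeddingStore,
        annots: AnnotationSet,
        train_ids: list[str],
        val_ids: list[str],
        vocab: list[str] | None = None,
        min_count: int = 1,
        architecture: str = "GAT",
        k: int = 100,
        min_conf: float | None = None,
        num_layers: int = 2,
        hidden_dim: int = 64,
        attention_heads: int = 4,
        dropout_rate: float = 0.3,
        missing_features: str = "zero",
        loss_config: LossConfig | None = None,
    ):
        super().__init__(annots, train_ids, val_ids, vocab, min_count, loss_config)
        self.table = table
        self.feature_store = feature_store
        self.k = k
        self.min_conf = min_conf
        self.missing_features = missing_features
        self._graph_cache: dict[str, object] = {}
        self.spec = GnnConfig(
            input_dim=feature_store.dim,
            output_dim=len(self.vocab),
            architecture=architecture,
            num_layers=num_layers,
            hidden_dim=hidden_dim,
            attention_heads=attention_heads,
            dropout_rate=dropout_rate,
        )

    def _inputs_for(self, ids: list[str]):
        out = []
        for protein in ids:
            g = self._graph_cache.get(protein)
            if g is None:
                g = attach_features(
                    build_ego_graph(
                        self.table, protein, k=self.k, min_conf=self.min_conf
                    ),
                    self.feature_store,
                    missing=self.missing_features,
                )
                self._graph_cache[protein] = g
            out.append(g)
        return out


class FunctionModelResults:
    """Trained parameters plus history and prediction for one modality."""

    def __init__(self, model, params, history: TrainHistory, train_config):
        self.model = model
        self.params = params
        self.history = history
        self.train_config = train_config

    @property
    def vocab(self) -> list[str]:
        return self.model.vocab

    @property
    def best_val_fmax(self) -> float:
        return self.history.val_fmax[self.history.best_epoch]

    @property
    def best_val_loss(self) -> float:
        return self.history.val_loss[self.history.best_epoch]

    def predict(self, ids: list[str]) -> ScoreMatrix:
        """Probability scores for the given proteins over the fitted
        vocabulary (logistic transform of eval-mode logits)."""
        return predict(
            self.params, self.model.spec, self.model._inputs_for(list(ids)),
            list(ids), self.vocab,
        )

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def summary(self) -> str:
        spec = self.model.spec
        kind = type(spec).__name__
        lines = [
            "Function prediction model",
            "=" * 40,
            f"spec              {kind}",
        ]
        if isinstance(spec, GnnConfig):
            lines.append(f"architecture      {spec.architecture}")
        lines += [
            f"input dim         {spec.input_dim}",
            f"terms             {len(self.vocab)}",
            f"parameters        {self.n_parameters()}",
            f"training proteins {len(self.model.train_ids)}",
            f"epochs run        {self.history.n_epochs}",
            f"best epoch        {self.history.best_epoch}",
            f"val Fmax (best)   {self.best_val_fmax:.4f}",
            f"val loss (best)   {self.best_val_loss:.4f}",
            f"contrastive alpha {self.model.loss_config.alpha}",
            f"seed              {self.train_config.seed}",
        ]
        return "\n".join(lines)
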