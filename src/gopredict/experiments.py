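"""Frozen desk-scale experiments on the synthetic scenarios.

These functions pin down the package's standard self-validation
experiments — label recovery on separable data, null calibration against
the Naive baseline, the interaction-signal (homophily) comparison, the
three-modality ensemble comparison, and the contrastive-gain trend — with
fixed problem sizes and training settings, so tests and the reproduction
script measure the same quantities.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .data_io import split_dataset
from .evaluation import fmax, fmax_arrays, naive_baseline
from .losses import LossConfig
from .modeling import EmbeddingFunctionModel, GraphFunctionModel, label_matrix
from .ontology import AnnotationSet
from .seeds import substream, substream_seed
from .synthetic import (
    SCENARIO_CONFIGS,
    SynthConfig,
    generate_annotations,
    generate_dag,
    generate_embeddings,
    generate_ppi,
    scenario,
    shuffle_edges,
)
from .training import TrainConfig, ensemble_average

#: condition for the interaction-signal experiment: the label signal lives
#: in the (purely within-group) neighbourhood, individual node features are
#: weak and noisy, latent groups near-balanced
HOMOPHILY_CONFIG = SynthConfig(
    n_terms=30, dag_depth=3, n_proteins=300, n_latent_functions=5,
    labels_per_protein=3.0, embed_dim_a=24, embed_dim_b=24,
    signal_strength=0.5, noise_sd=4.0, ppi_homophily=1.0,
    mean_degree=16.0, function_balance=10.0,
)

#: condition for the contrastive-gain trend: separable but moderately noisy
CONTRASTIVE_CONFIG = replace(
    SCENARIO_CONFIGS["A"], signal_strength=1.5, noise_sd=2.0
)


def _test_fmax(results, ids, annots) -> float:
    y = label_matrix(annots, ids, results.vocab) > 0.5
    return fmax_arrays(results.predict(ids).values, y).fmax


def recovery_experiment(seed: int, max_epochs: int = 50) -> dict:
    """Scenario A: an MLP on high-signal embeddings should recover the
    labels nearly perfectly (held-out Fmax >= 0.9)."""
    b = scenario("A", seed=seed)
    res = EmbeddingFunctionModel(
        b.store_a, b.annotations, b.train_ids, b.val_ids
    ).fit(TrainConfig(max_epochs=max_epochs, seed=seed))
    return {
        "test_fmax": _test_fmax(res, b.test_ids, b.annotations),
        "epochs_run": res.history.n_epochs,
    }


def null_experiment(seed: int, max_epochs: int = 30) -> dict:
    """Scenario B: with zero label signal, a trained model should land at
    the Naive frequency baseline's Fmax."""
    b = scenario("B", seed=seed)
    res = EmbeddingFunctionModel(
        b.store_a, b.annotations, b.train_ids, b.val_ids
    ).fit(TrainConfig(max_epochs=max_epochs, seed=seed))
    model_fmax = _test_fmax(res, b.test_ids, b.annotations)
    train_annots = AnnotationSet(
        {p: b.annotations.annotations[p] for p in b.train_ids}, b.annotations.namespace
    )
    truth = AnnotationSet(
        {p: b.annotations.annotations[p] for p in b.test_ids}, b.annotations.namespace
    )
    naive_fmax = fmax(naive_baseline(train_annots, b.test_ids), truth).fmax
    return {
        "model_fmax": model_fmax,
        "naive_fmax": naive_fmax,
        "abs_difference": abs(model_fmax - naive_fmax),
    }


def homophily_experiment(seed: int, max_epochs: int = 50) -> dict:
    """GAT on homophilous ego-graphs vs. the same model on edge-shuffled
    graphs; the held-out set is the val+test 20% (early stopping is inert
    here: patience equals the epoch budget)."""
    cfg = replace(HOMOPHILY_CONFIG, seed=seed)
    dag = generate_dag(cfg)
    annots = generate_annotations(dag, cfg)
    store = generate_embeddings(annots, dag, "b", cfg)
    ppi = generate_ppi(annots, cfg)
    ids = sorted(annots.annotations)
    train_ids, val_ids, test_ids = split_dataset(
        ids, (0.8, 0.1, 0.1), seed=substream_seed(seed, "split")
    )
    held = val_ids + test_ids
    out = {}
    for tag, table in (
        ("homophilous", ppi),
        ("shuffled", shuffle_edges(ppi, substream(seed, "edge-shuffle"))),
    ):
        model = GraphFunctionModel(
            table, store, annots, train_ids, val_ids,
            architecture="GAT", k=12, num_layers=2, hidden_dim=32,
            attention_heads=4, dropout_rate=0.0,
        )
        res = model.fit(
            TrainConfig(max_epochs=max_epochs, seed=seed,
                        early_stopping_patience=max_epochs)
        )
        out[tag] = _test_fmax(res, held, annots)
    out["gain"] = out["homophilous"] - out["shuffled"]
    return out


def ensemble_experiment(seed: int, mlp_epochs: int = 30, gnn_epochs: int = 20) -> dict:
    """Scenario C: three weak complementary modalities; the equal-weight
    ensemble should not fall more than a whisker below any single model."""
    b = scenario("C", seed=seed)
    cfg = TrainConfig(max_epochs=mlp_epochs, seed=seed)
    res_a = EmbeddingFunctionModel(
        b.store_a, b.annotations, b.train_ids, b.val_ids
    ).fit(cfg)
    vocab = res_a.vocab
    res_b = EmbeddingFunctionModel(
        b.store_b, b.annotations, b.train_ids, b.val_ids, vocab=vocab
    ).fit(cfg)
    res_g = GraphFunctionModel(
        b.ppi, b.store_b, b.annotations, b.train_ids, b.val_ids, vocab=vocab,
        architecture="GAT", k=10, num_layers=2, hidden_dim=32,
    ).fit(TrainConfig(max_epochs=gnn_epochs, seed=seed))
    y = label_matrix(b.annotations, b.test_ids, vocab) > 0.5
    scores = {
        "sequence": res_a.predict(b.test_ids),
        "structure": res_b.predict(b.test_ids),
        "graph": res_g.predict(b.test_ids),
    }
    out = {
        name: fmax_arrays(s.values, y).fmax for name, s in scores.items()
    }
    ens = ensemble_average(list(scores.values()))
    out["ensemble"] = fmax_arrays(ens.values, y).fmax
    out["min_single_gap"] = out["ensemble"] - max(
        out["sequence"], out["structure"], out["graph"]
    )
    return out


def contrastive_gain_experiment(
    seeds, alpha: float = 0.1, max_epochs: int = 30
) -> dict:
    """Fmax(alpha) - Fmax(0) on moderately noisy separable data, per seed.

    Reports the per-seed differences, their mean and a normal-approximation
    95% CI; the sign is an empirical observation, not a guarantee."""
    diffs = []
    for seed in seeds:
        cfg = replace(CONTRASTIVE_CONFIG, seed=seed)
        dag = generate_dag(cfg)
        annots = generate_annotations(dag, cfg)
        store = generate_embeddings(annots, dag, "a", cfg)
        ids = sorted(annots.annotations)
        train_ids, val_ids, test_ids = split_dataset(
            ids, (0.8, 0.1, 0.1), seed=substream_seed(seed, "split")
        )
        fvals = {}
        for a in (alpha, 0.0):
            res = EmbeddingFunctionModel(
                store, annots, train_ids, val_ids,
                loss_config=LossConfig(alpha=a),
            ).fit(TrainConfig(max_epochs=max_epochs, seed=seed))
            fvals[a] = _test_fmax(res, test_ids, annots)
        diffs.append(fvals[alpha] - fvals[0.0])
    diffs = np.asarray(diffs)
    se = diffs.std(ddof=1) / np.sqrt(len(diffs)) if len(diffs) > 1 else np.nan
    mean = float(diffs.mean())
    return {
        "per_seed_diff": [float(d) for d in diffs],
        "mean_diff": mean,
        "ci95": (mean - 1.96 * float(se), mean + 1.96 * float(se)),
        "positive_fraction": float((diffs > 0).mean()),
    }
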