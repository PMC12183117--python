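"""Synthetic ontology / annotation / embedding / PPI generator.

The generator emulates the structure of the real inputs — a rooted GO-like
DAG, multi-label annotations organized by latent functional groups, two
embedding "modalities" carrying label signal plus Gaussian noise, and a
homophilous PPI network in which interacting proteins tend to share
function — so the whole pipeline is trainable and testable offline.

The embedding model is deliberately simple (a seeded linear projection of
the label vector plus isotropic noise): strong enough signal makes labels
recoverable by construction, zero signal yields an exact null.  It is a
stand-in for protein-language-model geometry, not a simulator of it.

Three frozen scenarios pin down the study conditions used by the tests and
the acceptance script:

* **A** — high-signal separable data (label recovery should be nearly
  perfect);
* **B** — pure-noise null (nothing beyond the Naive frequency baseline
  should be learnable);
* **C** — three weak, complementary modalities (the regime where the
  ensemble is expected to help).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import InteractionTable, ProteinRecord
from .embeddings import EmbeddingStore
from .errors import ValidationError
from .ontology import AnnotationSet, GoDag, propagate_annotations
from .seeds import substream

_AMINO = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SynthConfig:
    n_terms: int = 40
    dag_depth: int = 3
    n_proteins: int = 300
    n_latent_functions: int = 5
    labels_per_protein: float = 3.0
    embed_dim_a: int = 32
    embed_dim_b: int = 32
    signal_strength: float = 1.0
    noise_sd: float = 1.0
    ppi_homophily: float = 0.9
    mean_degree: float = 8.0
    #: Dirichlet concentration of the latent-function prevalences; large
    #: values give near-equal group sizes, 1.0 a flat Dirichlet draw
    function_balance: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_terms", "dag_depth", "n_proteins", "n_latent_functions",
                     "embed_dim_a", "embed_dim_b"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.n_terms < self.dag_depth:
            raise ValidationError("n_terms must be >= dag_depth")
        if not (0.0 <= self.ppi_homophily <= 1.0):
            raise ValidationError("ppi_homophily must be in [0, 1]")
        if self.signal_strength < 0 or self.noise_sd < 0:
            raise ValidationError("signal_strength and noise_sd must be >= 0")


@dataclass
class SyntheticAnnotations(AnnotationSet):
    """An annotation set that remembers each protein's latent function."""

    latent: dict[str, int] = field(default_factory=dict)


def _term_id(i: int) -> str:
    return f"GO:9{i:06d}"


def generate_dag(config: SynthConfig) -> GoDag:
    """A layered single-namespace rooted DAG: the root alone in layer 0,
    the remaining terms spread over ``dag_depth`` layers, each term with
    1-2 parents drawn from the layer above."""
    rng = substream(config.seed, "dag")
    root = _term_id(0)
    terms = [_term_id(i) for i in range(config.n_terms)]
    layers: list[list[str]] = [[root]]
    rest = terms[1:]
    n_layers = min(config.dag_depth, max(len(rest), 1))
    if rest:
        sizes = [len(rest) // n_layers] * n_layers
        for i in range(len(rest) - sum(sizes)):
            sizes[i % n_layers] += 1
        start = 0
        for s in sizes:
            layers.append(rest[start : start + s])
            start += s
    parents: dict[str, set[str]] = {t: set() for t in terms}
    for depth in range(1, len(layers)):
        above = layers[depth - 1]
        for term in layers[depth]:
            k = 1 if len(above) == 1 else int(rng.integers(1, 3))
            chosen = rng.choice(len(above), size=min(k, len(above)), replace=False)
            parents[term] = {above[int(c)] for c in chosen}
    namespace = {t: "BP" for t in terms}
    return GoDag(terms=set(terms), namespace=namespace, parents=parents)


def _leaves(dag: GoDag) -> list[str]:
    has_child: set[str] = set()
    for child, ps in dag.parents.items():
        if ps:
            has_child |= ps
    return sorted(dag.terms - has_child)


def generate_annotations(dag: GoDag, config: SynthConfig) -> SyntheticAnnotations:
    """Latent-function structured multi-label annotations.

    Function prevalences are Dirichlet-distributed; each latent function
    owns a characteristic set of leaf terms; each protein draws a function,
    then a Poisson(labels_per_protein) number of leaves (>= 1) from that
    set, and its term set is the ancestor closure of those leaves with the
    root removed.
    """
    rng = substream(config.seed, "annotations")
    leaves = _leaves(dag)
    char_size = min(len(leaves), max(2, math.ceil(2 * config.labels_per_protein)))
    char_sets = []
    for _ in range(config.n_latent_functions):
        chosen = rng.choice(len(leaves), size=char_size, replace=False)
        char_sets.append([leaves[int(c)] for c in chosen])
    prevalence = rng.dirichlet(
        np.full(config.n_latent_functions, config.function_balance)
    )
    annotations: dict[str, set[str]] = {}
    latent: dict[str, int] = {}
    for i in range(config.n_proteins):
        protein = f"P{i:05d}"
        f = int(rng.choice(config.n_latent_functions, p=prevalence))
        latent[protein] = f
        pool = char_sets[f]
        n_leaves = min(len(pool), max(1, int(rng.poisson(config.labels_per_protein))))
        chosen = rng.choice(len(pool), size=n_leaves, replace=False)
        annotations[protein] = {pool[int(c)] for c in chosen}
    raw = SyntheticAnnotations(annotations=annotations, namespace="BP", latent=latent)
    closed = propagate_annotations(dag, raw)
    return SyntheticAnnotations(
        annotations=closed.annotations, namespace="BP", latent=latent
    )


def label_vocabulary(dag: GoDag) -> list[str]:
    """All non-root terms in id order — the label-vector coordinate system
    the generator's projections use."""
    return sorted(dag.terms - dag.roots)


def generate_embeddings(
    annots: AnnotationSet,
    dag: GoDag,
    modality: str,
    config: SynthConfig,
) -> EmbeddingStore:
    """Linear-signal-plus-noise embeddings for one modality.

    vector = signal_strength * (W_modality @ label_vector) + N(0, noise_sd^2)
    with W_modality a seeded random projection distinct per modality, so
    the two modalities carry the same label information through different,
    complementary coordinates.  signal_strength = 0 yields pure noise.
    """
    if modality not in {"a", "b"}:
        raise ValueError(f"unknown modality: {modality!r}")
    dim = config.embed_dim_a if modality == "a" else config.embed_dim_b
    vocab = label_vocabulary(dag)
    t_index = {t: j for j, t in enumerate(vocab)}
    proj_rng = substream(config.seed, f"projection-{modality}")
    W = proj_rng.normal(0.0, 1.0 / np.sqrt(max(len(vocab), 1)), size=(len(vocab), dim))
    noise_rng = substream(config.seed, f"noise-{modality}")
    vectors: dict[str, np.ndarray] = {}
    for protein in sorted(annots.annotations):
        y = np.zeros(len(vocab))
        for t in annots.annotations[protein]:
            if t in t_index:
                y[t_index[t]] = 1.0
        vec = config.signal_strength * (y @ W)
        vec = vec + noise_rng.normal(0.0, config.noise_sd, size=dim)
        vectors[protein] = vec.astype(np.float32)
    return EmbeddingStore(dim=dim, vectors=vectors, modality=f"synthetic-{modality}")


def generate_ppi(
    annots: SyntheticAnnotations, config: SynthConfig
) -> InteractionTable:
    """Homophilous PPI network.

    Pair sampling weights are ``h`` within a latent-function group and
    ``1 - h`` across groups, scaled so the expected mean degree matches
    ``mean_degree``; same-function edges get higher confidences.
    """
    rng = substream(config.seed, "ppi")
    proteins = sorted(annots.annotations)
    n = len(proteins)
    latent = np.array([annots.latent[p] for p in proteins])
    same = latent[:, None] == latent[None, :]
    iu = np.triu_indices(n, k=1)
    same_u = same[iu]
    h = config.ppi_homophily
    n_within = int(same_u.sum())
    n_cross = same_u.size - n_within
    target_edges = config.mean_degree * n / 2.0
    denom = h * n_within + (1.0 - h) * n_cross
    c = target_edges / denom if denom > 0 else 0.0
    p = np.where(same_u, min(1.0, c * h), min(1.0, c * (1.0 - h)))
    draws = rng.random(same_u.size) < p
    rows = []
    conf_rng = substream(config.seed, "ppi-conf")
    for k in np.flatnonzero(draws):
        i, j = int(iu[0][k]), int(iu[1][k])
        if same_u[k]:
            conf = conf_rng.uniform(0.6, 1.0)
        else:
            conf = conf_rng.uniform(0.3, 0.7)
        rows.append((proteins[i], proteins[j], float(conf)))
    return InteractionTable.from_rows(rows)


def shuffle_edges(table: InteractionTable, rng: np.random.Generator) -> InteractionTable:
    """Degree-destroying null: rewire every edge to uniformly random
    distinct endpoints, keeping the edge count and confidence values."""
    proteins = sorted(table.proteins())
    n = len(proteins)
    rows = []
    for _, _, conf in table:
        i = int(rng.integers(n))
        j = int(rng.integers(n - 1))
        if j >= i:
            j += 1
        rows.append((proteins[i], proteins[j], conf))
    return InteractionTable.from_rows(rows)


def dummy_records(annots: AnnotationSet, seed: int, length: int = 50):
    """Random amino-acid sequences for FASTA round-trips."""
    rng = substream(seed, "sequences")
    records = []
    for protein in sorted(annots.annotations):
        seq = "".join(_AMINO[int(i)] for i in rng.integers(0, 20, size=length))
        records.append(ProteinRecord(id=protein, sequence=seq))
    return records


def write_obo(dag: GoDag, sink) -> None:
    """Serialize a (synthetic) DAG as minimal OBO 1.2 text."""
    close = False
    if not hasattr(sink, "write"):
        sink = open(sink, "w")
        close = True
    ns_long = {"BP": "biological_process", "MF": "molecular_function",
               "CC": "cellular_component"}
    try:
        sink.write("format-version: 1.2\nontology: synthetic\n")
        for term in sorted(dag.terms):
            sink.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            sink.write(f"namespace: {ns_long[dag.namespace[term]]}\n")
            for p in sorted(dag.parents[term]):
                sink.write(f"is_a: {p} ! {p}\n")
    finally:
        if close:
            sink.close()


# --------------------------------------------------------------------------
# frozen scenarios

SCENARIO_CONFIGS: dict[str, SynthConfig] = {
    # high-signal separable: labels decodable almost perfectly
    "A": SynthConfig(
        n_terms=30, dag_depth=3, n_proteins=300, n_latent_functions=5,
        labels_per_protein=3.0, embed_dim_a=32, embed_dim_b=32,
        signal_strength=4.0, noise_sd=1.0, ppi_homophily=0.95, mean_degree=8.0,
    ),
    # pure-noise null: embeddings carry no label information
    "B": SynthConfig(
        n_terms=30, dag_depth=3, n_proteins=300, n_latent_functions=5,
        labels_per_protein=3.0, embed_dim_a=32, embed_dim_b=32,
        signal_strength=0.0, noise_sd=1.0, ppi_homophily=0.5, mean_degree=8.0,
    ),
    # three weak complementary modalities
    "C": SynthConfig(
        n_terms=30, dag_depth=3, n_proteins=300, n_latent_functions=5,
        labels_per_protein=3.0, embed_dim_a=24, embed_dim_b=24,
        signal_strength=1.0, noise_sd=1.5, ppi_homophily=0.9, mean_degree=8.0,
    ),
}

SPLIT_FRACTIONS = (0.8, 0.1, 0.1)


@dataclass
class ScenarioBundle:
    name: str
    config: SynthConfig
    dag: GoDag
    annotations: SyntheticAnnotations  # ancestor-propagated
    store_a: EmbeddingStore
    store_b: EmbeddingStore
    ppi: InteractionTable
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]


def scenario(name: str, seed: int) -> ScenarioBundle:
    """Generate a full train/val/test bundle for scenario A, B or C."""
    if name not in SCENARIO_CONFIGS:
        raise ValueError(f"unknown scenario: {name!r} (expected A, B or C)")
    from .data_io import split_dataset  # local import to avoid a cycle

    config = replace(SCENARIO_CONFIGS[name], seed=seed)
    dag = generate_dag(config)
    annots = generate_annotations(dag, config)
    store_a = generate_embeddings(annots, dag, "a", config)
    store_b = generate_embeddings(annots, dag, "b", config)
    ppi = generate_ppi(annots, config)
    ids = sorted(annots.annotations)
    from .seeds import substream_seed

    train_ids, val_ids, test_ids = split_dataset(
        ids, SPLIT_FRACTIONS, seed=substream_seed(seed, "split")
    )
    return ScenarioBundle(
        name=name, config=config, dag=dag, annotations=annots,
        store_a=store_a, store_b=store_b, ppi=ppi,
        train_ids=train_ids, val_ids=val_ids, test_ids=test_ids,
    )
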