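"""Query-centered PPI ego-graph construction.

Each query protein gets a subgraph of its interaction neighbourhood: the
top-k partners by interaction confidence (k = 100 by default), every
interaction among the selected proteins, and a self-loop on every node so
that proteins with no interactions at all remain representable as a
single-node graph.  An optional confidence floor reproduces the
high-confidence-only variant (scores > 0.7).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np

from .containers import InteractionTable
from .embeddings import EmbeddingStore
from .errors import MissingIdError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class EgoGraph:
    """A query-centered PPI subgraph.

    ``nodes`` lists protein ids with the center first.  ``edges`` holds
    (i, j, confidence) node-index triples for the undirected interaction
    pairs (i < j) plus a self-loop (i, i, 1.0) on every node.  ``features``
    is an optional n x d node-feature matrix.
    """

    center: str
    nodes: list[str]
    edges: list[tuple[int, int, float]]
    features: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.nodes or self.nodes[0] != self.center:
            raise ValidationError("ego-graph nodes must start with the center")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValidationError("duplicate nodes in ego-graph")
        n = len(self.nodes)
        loops = set()
        for i, j, conf in self.edges:
            if not (0 <= i < n and 0 <= j < n):
                raise ValidationError(f"edge ({i}, {j}) out of node range")
            if not (0.0 <= conf <= 1.0):
                raise ValidationError(f"edge ({i}, {j}) confidence {conf} not in [0,1]")
            if i == j:
                loops.add(i)
        if loops != set(range(n)):
            raise ValidationError("every node must carry a self-loop")
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=np.float32)
            if self.features.shape[0] != n or self.features.ndim != 2:
                raise ValidationError(
                    f"feature matrix shape {self.features.shape} does not match "
                    f"{n} nodes"
                )

    @property
    def num_nodes(self) -> int:
        return len(self.nodes)

    def directed_arcs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(src, dst, conf) arrays with each undirected edge materialized as
        two directed arcs; self-loops appear once."""
        src, dst, conf = [], [], []
        for i, j, c in self.edges:
            src.append(i)
            dst.append(j)
            conf.append(c)
            if i != j:
                src.append(j)
                dst.append(i)
                conf.append(c)
        return (
            np.asarray(src, dtype=np.int64),
            np.asarray(dst, dtype=np.int64),
            np.asarray(conf, dtype=np.float32),
        )


def build_ego_graph(
    table: InteractionTable,
    query: str,
    k: int = 100,
    min_conf: float | None = None,
    star_only: bool = False,
    apply_before_topk: bool = False,
) -> EgoGraph:
    """Build the ego-graph of *query* from an interaction table.

    Neighbours are ranked by (confidence descending, partner id ascending)
    and truncated to the top *k*; *min_conf*, when given, then drops
    selected neighbours whose edge to the query is <= min_conf (set
    *apply_before_topk* to filter the candidate list before ranking
    instead).  Edges among the selected neighbours are included unless
    *star_only* is set.  A query absent from the table yields a single-node
    self-loop graph.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if min_conf is not None and not (0.0 <= min_conf <= 1.0):
        raise ValueError("min_conf must be within [0, 1]")

    partners = table.neighbors(query)
    if min_conf is not None and apply_before_topk:
        partners = [(p, c) for p, c in partners if c > min_conf]
    partners.sort(key=lambda pc: (-pc[1], pc[0]))
    partners = partners[:k]
    if min_conf is not None and not apply_before_topk:
        partners = [(p, c) for p, c in partners if c > min_conf]

    nodes = [query] + [p for p, _ in partners]
    index = {p: i for i, p in enumerate(nodes)}
    edges: list[tuple[int, int, float]] = [(i, i, 1.0) for i in range(len(nodes))]
    for p, c in partners:
        i, j = sorted((index[query], index[p]))
        edges.append((i, j, c))
    if not star_only:
        selected = set(nodes[1:])
        for a, b, c in table:
            if a in selected and b in selected:
                i, j = sorted((index[a], index[b]))
                edges.append((i, j, c))
    return EgoGraph(center=query, nodes=nodes, edges=edges)


def attach_features(
    graph: EgoGraph, store: EmbeddingStore, missing: str = "error"
) -> EgoGraph:
    """Attach each node's embedding vector as its feature row.

    ``missing="zero"`` substitutes a zero vector for absent ids (logged);
    ``missing="error"`` raises naming the id.
    """
    if missing not in {"error", "zero"}:
        raise ValueError(f"unknown missing policy: {missing!r}")
    rows = []
    for node in graph.nodes:
        if node in store:
            rows.append(store.get(node))
        elif missing == "zero":
            logger.warning("no embedding for node %s; using zeros", node)
            rows.append(np.zeros(store.dim, dtype=np.float32))
        else:
            raise MissingIdError(f"no embedding for node: {node}")
    return EgoGraph(
        center=graph.center,
        nodes=list(graph.nodes),
        edges=list(graph.edges),
        features=np.stack(rows),
    )


def save_graphs(graphs: list[EgoGraph], path) -> None:
    """Write a batch of featured ego-graphs to a directory: a JSON index of
    node ids and edges plus one .npy feature block per graph."""
    path = os.fspath(path)
    os.makedirs(path, exist_ok=True)
    index = []
    for g_i, g in enumerate(graphs):
        entry = {"center": g.center, "nodes": g.nodes,
                 "edges": [[i, j, float(c)] for i, j, c in g.edges]}
        if g.features is not None:
            np.save(os.path.join(path, f"features_{g_i:06d}.npy"), g.features)
            entry["features"] = f"features_{g_i:06d}.npy"
        index.append(entry)
    with open(os.path.join(path, "graphs.json"), "w") as f:
        json.dump(index, f)


def load_graphs(path) -> list[EgoGraph]:
    path = os.fspath(path)
    with open(os.path.join(path, "graphs.json")) as f:
        index = json.load(f)
    graphs = []
    for entry in index:
        features = None
        if "features" in entry:
            features = np.load(os.path.join(path, entry["features"]))
        graphs.append(
            EgoGraph(
                center=entry["center"],
                nodes=entry["nodes"],
                edges=[(int(i), int(j), float(c)) for i, j, c in entry["edges"]],
                features=features,
            )
        )
    return graphs
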