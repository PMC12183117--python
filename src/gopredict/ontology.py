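"""Gene Ontology handling: OBO parsing, ancestor queries and true-path
propagation of annotations and prediction scores.

The Gene Ontology is a rooted DAG in three disjoint sub-ontologies
(biological process, molecular function, cellular component).  Under the
true-path rule, annotation with a term implies annotation with every
ancestor of that term; CAFA-style evaluation presumes both ground truth and
prediction scores are consistent with that rule.  This module provides:

* :func:`parse_obo` — read an OBO flat file into a :class:`GoDag`
  (``is_a`` edges only by default; obsolete terms dropped),
* :func:`ancestors` / :func:`descendants` — transitive closures,
* :func:`propagate_annotations` — close each protein's term set under
  ancestors, dropping namespace roots,
* :func:`propagate_scores` — make scores monotone along ``is_a`` edges by
  taking, for every term, the max over the term and all its descendants.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet

from .containers import ScoreMatrix
from .errors import MissingIdError, ParseError, ValidationError

#: canonical short codes for the three GO namespaces
NAMESPACE_CODES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
    "BP": "BP",
    "MF": "MF",
    "CC": "CC",
    "bp": "BP",
    "mf": "MF",
    "cc": "CC",
}


@dataclass
class GoDag:
    """The ontology DAG: term ids, per-term namespace, ``is_a`` parent links.

    ``roots`` holds the namespace root terms (terms with no parents).  The
    parent graph is validated to be acyclic and namespace-consistent on
    construction.
    """

    terms: set[str]
    namespace: dict[str, str]
    parents: dict[str, set[str]]
    roots: set[str] = field(default_factory=set)
    _ancestor_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        for term in self.terms:
            if term not in self.namespace:
                raise ValidationError(f"term {term} has no namespace")
            self.parents.setdefault(term, set())
        for term, ps in self.parents.items():
            for p in ps:
                if p not in self.terms:
                    raise ValidationError(f"term {term} has unknown parent {p}")
                if self.namespace[p] != self.namespace[term]:
                    raise ValidationError(
                        f"is_a edge {term} -> {p} crosses namespaces "
                        f"({self.namespace[term]} -> {self.namespace[p]})"
                    )
        graph = self.to_networkx()
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValidationError(f"is_a graph contains a cycle: {cycle}")
        if not self.roots:
            self.roots = {t for t in self.terms if not self.parents[t]}

    def to_networkx(self) -> nx.DiGraph:
        """Directed graph with child -> parent edges."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(
            (child, parent) for child, ps in self.parents.items() for parent in ps
        )
        return g

    def ancestors(self, term: str) -> frozenset[str]:
        """Transitive closure over parents, excluding the term itself."""
        if term not in self.terms:
            raise MissingIdError(f"unknown term id: {term}")
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = list(self.parents[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents[t])
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result

    def descendants(self, term: str) -> frozenset[str]:
        """Transitive closure over children, excluding the term itself."""
        if term not in self.terms:
            raise MissingIdError(f"unknown term id: {term}")
        children: dict[str, list[str]] = {t: [] for t in self.terms}
        for child, ps in self.parents.items():
            for p in ps:
                children[p].append(child)
        out: set[str] = set()
        stack = list(children[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(children[t])
        return frozenset(out)

    def topological_order(self) -> list[str]:
        """Terms ordered children-before-parents."""
        return list(nx.topological_sort(self.to_networkx()))


@dataclass
class AnnotationSet:
    """Protein -> GO-term sets, all terms within one namespace."""

    annotations: dict[str, set[str]]
    namespace: str

    def __post_init__(self) -> None:
        self.namespace = NAMESPACE_CODES.get(self.namespace, self.namespace)
        if self.namespace not in {"BP", "MF", "CC"}:
            raise ValidationError(f"unknown namespace: {self.namespace!r}")

    def validate_against(self, dag: GoDag) -> None:
        for protein, terms in self.annotations.items():
            for t in terms:
                if t not in dag.terms:
                    raise ValidationError(
                        f"protein {protein}: term {t} not in ontology"
                    )
                if dag.namespace[t] != self.namespace:
                    raise ValidationError(
                        f"protein {protein}: term {t} is in namespace "
                        f"{dag.namespace[t]}, expected {self.namespace}"
                    )

    def proteins(self) -> list[str]:
        return list(self.annotations)

    def __len__(self) -> int:
        return len(self.annotations)


def parse_obo(stream, include_part_of: bool = False) -> GoDag:
    """Parse OBO 1.2/1.4 text into a :class:`GoDag`.

    Obsolete terms are dropped.  Only ``is_a`` edges are retained unless
    *include_part_of* is set, in which case ``relationship: part_of`` edges
    are treated like ``is_a``.  Raises :class:`ParseError` on malformed
    input and :class:`ValidationError` on a cyclic ``is_a`` graph.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    try:
        graph = obonet.read_obo(stream, ignore_obsolete=True)
    except ValueError as exc:
        raise ParseError(f"malformed OBO stanza: {exc}") from exc

    terms: set[str] = set(graph.nodes)
    namespace: dict[str, str] = {}
    parents: dict[str, set[str]] = {t: set() for t in terms}
    for term, data in graph.nodes(data=True):
        ns = data.get("namespace")
        if ns is None or ns not in NAMESPACE_CODES:
            raise ParseError(f"term {term}: missing or unknown namespace {ns!r}")
        namespace[term] = NAMESPACE_CODES[ns]
    keep = {"is_a"} | ({"part_of"} if include_part_of else set())
    for child, parent, rel in graph.edges(keys=True):
        if rel in keep and parent in terms:
            parents[child].add(parent)
    # part_of can cross namespaces (e.g. MF part_of BP); drop those edges
    if include_part_of:
        for child in parents:
            parents[child] = {
                p for p in parents[child] if namespace[p] == namespace[child]
            }
    return GoDag(terms=terms, namespace=namespace, parents=parents)


def ancestors(dag: GoDag, term: str) -> frozenset[str]:
    """Module-level alias for :meth:`GoDag.ancestors`."""
    return dag.ancestors(term)


def propagate_annotations(dag: GoDag, annots: AnnotationSet) -> AnnotationSet:
    """Close every protein's term set under ancestors (true-path rule).

    Namespace root terms are removed from the result; the operation is
    idempotent.  Terms outside the annotation set's namespace raise
    :class:`ValidationError`.
    """
    annots.validate_against(dag)
    out: dict[str, set[str]] = {}
    for protein, terms in annots.annotations.items():
        closed: set[str] = set()
        for t in terms:
            closed.add(t)
            closed |= dag.ancestors(t)
        out[protein] = closed - dag.roots
    return AnnotationSet(annotations=out, namespace=annots.namespace)


def propagate_scores(dag: GoDag, scores: ScoreMatrix) -> ScoreMatrix:
    """Max-propagate prediction scores up the DAG.

    Each term's score becomes the maximum over itself and all its
    descendants, so no ``is_a`` edge has parent < child.  Idempotent and
    never decreases any score.  Score columns must all be ontology terms of
    one namespace.
    """
    col_ns = set()
    for t in scores.terms:
        if t not in dag.terms:
            raise ValidationError(f"score column {t} not in ontology")
        col_ns.add(dag.namespace[t])
    if len(col_ns) > 1:
        raise ValidationError(f"score columns span namespaces {sorted(col_ns)}")

    col_index = {t: j for j, t in enumerate(scores.terms)}
    n = len(scores.proteins)
    # per-protein running max over all DAG terms, relaxed children-first
    vals: dict[str, np.ndarray] = {}
    order = dag.topological_order()  # children before parents
    neg = np.full(n, -np.inf)
    for t in order:
        v = scores.values[:, col_index[t]].copy() if t in col_index else neg.copy()
        vals[t] = v
    for child in order:
        for parent in dag.parents[child]:
            np.maximum(vals[parent], vals[child], out=vals[parent])
    new = scores.values.copy()
    for t, j in col_index.items():
        np.maximum(new[:, j], vals[t], out=new[:, j])
    return ScoreMatrix(list(scores.proteins), list(scores.terms), new)
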