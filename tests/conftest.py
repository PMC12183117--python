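"""Shared fixtures: toy ontologies, random DAG/score generators."""

from __future__ import annotations

import numpy as np
import pytest

from gopredict.containers import InteractionTable, ScoreMatrix
from gopredict.ontology import AnnotationSet, GoDag

TOY_OBO = """format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: leaf A
namespace: biological_process
is_a: GO:0000002 ! B
is_a: GO:0000003 ! C

[Term]
id: GO:0000002
name: B
namespace: biological_process
is_a: GO:0000004 ! D

[Term]
id: GO:0000003
name: C
namespace: biological_process
is_a: GO:0000004 ! D

[Term]
id: GO:0000004
name: D (root)
namespace: biological_process

[Term]
id: GO:0000005
name: mf term
namespace: molecular_function
is_a: GO:0000006 ! mf root

[Term]
id: GO:0000006
name: mf root
namespace: molecular_function

[Term]
id: GO:0000007
name: obsolete term
namespace: biological_process
is_obsolete: true
"""


@pytest.fixture(scope="session")
def toy_obo_text() -> str:
    return TOY_OBO


@pytest.fixture(scope="session")
def diamond_dag() -> GoDag:
    """A -> {B, C} -> D(root), single namespace."""
    return GoDag(
        terms={"A", "B", "C", "D"},
        namespace={t: "BP" for t in "ABCD"},
        parents={"A": {"B", "C"}, "B": {"D"}, "C": {"D"}, "D": set()},
    )


@pytest.fixture(scope="session")
def chain_dag() -> GoDag:
    """A -> B -> root."""
    return GoDag(
        terms={"A", "B", "root"},
        namespace={"A": "BP", "B": "BP", "root": "BP"},
        parents={"A": {"B"}, "B": {"root"}, "root": set()},
    )


def random_dag(rng: np.random.Generator, n_terms: int, namespace: str = "BP") -> GoDag:
    """A random rooted single-namespace DAG: term i's parents drawn from
    earlier terms, term 0 the root."""
    terms = [f"T{i:03d}" for i in range(n_terms)]
    parents: dict[str, set[str]] = {terms[0]: set()}
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(i, 3) + 1))
        chosen = rng.choice(i, size=k, replace=False)
        parents[terms[i]] = {terms[int(c)] for c in chosen}
    return GoDag(
        terms=set(terms),
        namespace={t: namespace for t in terms},
        parents=parents,
    )


def random_scores(
    rng: np.random.Generator, proteins: int, terms: list[str]
) -> ScoreMatrix:
    ids = [f"P{i:03d}" for i in range(proteins)]
    return ScoreMatrix(ids, list(terms), rng.random((proteins, len(terms))))


def random_interactions(
    rng: np.random.Generator, n_proteins: int, n_edges: int
) -> InteractionTable:
    ids = [f"P{i:03d}" for i in range(n_proteins)]
    rows = []
    for _ in range(n_edges):
        i, j = rng.choice(n_proteins, size=2, replace=False)
        rows.append((ids[int(i)], ids[int(j)], float(rng.random())))
    return InteractionTable.from_rows(rows)


def truth_from_matrix(y: np.ndarray, proteins: list[str], terms: list[str]):
    annots = {
        p: {terms[j] for j in np.flatnonzero(y[i])} for i, p in enumerate(proteins)
    }
    return AnnotationSet(annotations=annots, namespace="BP")
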