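"""Readers and writers for the on-disk formats, plus deterministic splits.

Formats handled: FASTA (sequences), STRING protein-links tables,
protein->term annotation TSV and GAF 2.x, score-matrix TSV, and two-column
id-mapping TSV.  All readers are deterministic and all read/write pairs
round-trip.
"""

from __future__ import annotations

import gzip
import logging
import math
import os
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .containers import InteractionTable, ProteinRecord, ScoreMatrix
from .errors import ParseError
from .ontology import NAMESPACE_CODES, AnnotationSet, GoDag

logger = logging.getLogger(__name__)


def _open_text(source, mode: str = "rt"):
    """Accept a path (plain or .gz) or an open text stream."""
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    path = os.fspath(source)
    if path.endswith(".gz"):
        return gzip.open(path, mode), True
    return open(path, mode), True


def read_fasta(source) -> list[ProteinRecord]:
    """Read FASTA records; the header token before the first whitespace is
    the protein id.  Duplicate ids raise :class:`ParseError`."""
    stream, close = _open_text(source)
    try:
        records = []
        seen: set[str] = set()
        for rec in SeqIO.parse(stream, "fasta"):
            if rec.id in seen:
                raise ParseError(f"duplicate FASTA id: {rec.id}")
            seen.add(rec.id)
            records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq)))
        return records
    finally:
        if close:
            stream.close()


def write_fasta(records: Iterable[ProteinRecord], sink, width: int = 60) -> None:
    stream, close = _open_text(sink, "wt")
    try:
        for rec in records:
            stream.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, max(len(seq), 1), width):
                stream.write(seq[i : i + width] + "\n")
    finally:
        if close:
            stream.close()


def read_string_links(
    source,
    id_map: dict[str, str] | None = None,
    score_scale: str = "auto",
) -> InteractionTable:
    """Read a STRING protein-links file: whitespace-separated columns
    (protein1, protein2, combined_score), optional header row.

    *score_scale*: ``thousand`` divides scores by 1000 (STRING's 0-1000
    integer convention), ``unit`` takes them as-is, ``auto`` divides by 1000
    iff any score exceeds 1.  Rows whose ids are absent from *id_map* (when
    given) are dropped; the drop count is logged.
    """
    if score_scale not in {"auto", "unit", "thousand"}:
        raise ValueError(f"unknown score_scale: {score_scale!r}")
    stream, close = _open_text(source)
    try:
        raw: list[tuple[str, str, float]] = []
        for lineno, line in enumerate(stream, start=1):
            fields = line.split()
            if not fields or line.startswith("#"):
                continue
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: expected 3 columns, got {len(fields)}")
            a, b, score_str = fields[0], fields[1], fields[2]
            if lineno == 1 and not _is_number(score_str):
                continue  # header row
            try:
                score = float(score_str)
            except ValueError:
                raise ParseError(f"line {lineno}: non-numeric score {score_str!r}")
            raw.append((a, b, score))
    finally:
        if close:
            stream.close()

    if score_scale == "thousand" or (
        score_scale == "auto" and any(s > 1.0 for _, _, s in raw)
    ):
        raw = [(a, b, s / 1000.0) for a, b, s in raw]

    dropped = 0
    rows: list[tuple[str, str, float]] = []
    for a, b, s in raw:
        if id_map is not None:
            if a not in id_map or b not in id_map:
                dropped += 1
                continue
            a, b = id_map[a], id_map[b]
        rows.append((a, b, s))
    if dropped:
        logger.info("read_string_links: dropped %d unmappable rows", dropped)
    return InteractionTable.from_rows(rows)


def read_id_map(source) -> dict[str, str]:
    """Two-column TSV mapping external ids to protein ids."""
    stream, close = _open_text(source)
    try:
        mapping: dict[str, str] = {}
        for lineno, line in enumerate(stream, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"line {lineno}: expected 2 tab-separated columns")
            mapping[parts[0]] = parts[1]
        return mapping
    finally:
        if close:
            stream.close()


def read_annotations(source, dag: GoDag, namespace: str) -> AnnotationSet:
    """Read protein->term annotations, filtered to one namespace.

    Accepts a two-column TSV ``protein_id<TAB>term_id`` (optional header)
    or GAF 2.x (``!`` comments; protein id from column 2, term from column
    5; rows whose qualifier contains ``NOT`` dropped).  Unknown or
    off-namespace terms are dropped with a logged count.
    """
    ns = NAMESPACE_CODES.get(namespace)
    if ns is None:
        raise ValueError(f"unknown namespace: {namespace!r}")
    stream, close = _open_text(source)
    try:
        pairs: list[tuple[str, str]] = []
        for lineno, line in enumerate(stream, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if line.startswith("!"):
                continue  # GAF comment / header
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 15:  # GAF 2.x row
                qualifier = fields[3]
                if "NOT" in qualifier.split("|"):
                    continue
                pairs.append((fields[1], fields[4]))
            elif len(fields) >= 2:
                protein, term = fields[0].strip(), fields[1].strip()
                if lineno == 1 and not term.startswith("GO:") and term not in dag.terms:
                    continue  # header row
                pairs.append((protein, term))
            else:
                raise ParseError(f"line {lineno}: expected >=2 tab-separated columns")
    finally:
        if close:
            stream.close()

    annotations: dict[str, set[str]] = {}
    dropped = 0
    for protein, term in pairs:
        if term not in dag.terms or dag.namespace[term] != ns:
            dropped += 1
            continue
        annotations.setdefault(protein, set()).add(term)
    if dropped:
        logger.info("read_annotations: dropped %d off-namespace/unknown terms", dropped)
    if not annotations:
        logger.warning("read_annotations: no annotations for namespace %s", ns)
    return AnnotationSet(annotations=annotations, namespace=ns)


def write_annotations(annots: AnnotationSet, sink) -> None:
    stream, close = _open_text(sink, "wt")
    try:
        for protein in sorted(annots.annotations):
            for term in sorted(annots.annotations[protein]):
                stream.write(f"{protein}\t{term}\n")
    finally:
        if close:
            stream.close()


def split_dataset(
    ids: Sequence[str], fractions: Sequence[float], seed: int
) -> list[list[str]]:
    """Deterministic random partition of *ids* by *fractions*.

    Sizes are floor-based, with the remainder assigned to the first
    partition (the training split).  Shuffling is driven solely by *seed*.
    """
    fractions = list(fractions)
    if any(f <= 0 for f in fractions):
        raise ValueError("all fractions must be positive")
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError(f"fractions sum to {sum(fractions)}, expected 1")
    ids = list(ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    sizes = [int(len(ids) * f) for f in fractions]
    sizes[0] += len(ids) - sum(sizes)
    parts: list[list[str]] = []
    start = 0
    for s in sizes:
        parts.append(shuffled[start : start + s])
        start += s
    return parts


def write_scores(matrix: ScoreMatrix, sink) -> None:
    """TSV: header row of term ids, first column the protein id, scores in
    6-decimal fixed point."""
    stream, close = _open_text(sink, "wt")
    try:
        stream.write("protein_id\t" + "\t".join(matrix.terms) + "\n")
        for i, protein in enumerate(matrix.proteins):
            row = "\t".join(f"{v:.6f}" for v in matrix.values[i])
            stream.write(f"{protein}\t{row}\n")
    finally:
        if close:
            stream.close()


def read_scores(source) -> ScoreMatrix:
    stream, close = _open_text(source)
    try:
        header = stream.readline().rstrip("\n")
        if not header:
            raise ParseError("empty score file")
        terms = header.split("\t")[1:]
        proteins: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(stream, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(terms) + 1:
                raise ParseError(
                    f"line {lineno}: expected {len(terms) + 1} columns, "
                    f"got {len(fields)}"
                )
            proteins.append(fields[0])
            try:
                rows.append([float(v) for v in fields[1:]])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}")
        values = np.array(rows, dtype=float) if rows else np.zeros((0, len(terms)))
        return ScoreMatrix(proteins, terms, values)
    finally:
        if close:
            stream.close()


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False
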