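"""Plain data containers shared by the IO, ontology and model layers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MissingIdError, ValidationError

_ALLOWED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" "XBZU*")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier with an (optionally empty) amino-acid sequence."""

    id: str
    sequence: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein record has an empty id")
        bad = set(self.sequence.upper()) - _ALLOWED_RESIDUES
        if bad:
            raise ValidationError(
                f"protein {self.id!r}: invalid residue characters {sorted(bad)}"
            )


@dataclass
class InteractionTable:
    """Undirected protein-protein interactions with unit-scale confidences.

    Stored canonically: each pair appears once with ``a < b`` lexicographically,
    no self-pairs, confidence in [0, 1].  Duplicate pairs keep the maximum
    confidence seen.
    """

    pairs: dict[tuple[str, str], float] = field(default_factory=dict)

    @classmethod
    def from_rows(cls, rows) -> "InteractionTable":
        pairs: dict[tuple[str, str], float] = {}
        for a, b, conf in rows:
            if a == b:
                continue
            if not (0.0 <= conf <= 1.0):
                raise ValidationError(
                    f"interaction ({a}, {b}) confidence {conf} outside [0, 1]"
                )
            key = (a, b) if a < b else (b, a)
            prev = pairs.get(key)
            if prev is None or conf > prev:
                pairs[key] = conf
        return cls(pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return ((a, b, c) for (a, b), c in self.pairs.items())

    def neighbors(self, protein: str) -> list[tuple[str, float]]:
        """All interaction partners of *protein* with their confidences."""
        out = []
        for (a, b), c in self.pairs.items():
            if a == protein:
                out.append((b, c))
            elif b == protein:
                out.append((a, c))
        return out

    def proteins(self) -> set[str]:
        ids: set[str] = set()
        for a, b in self.pairs:
            ids.add(a)
            ids.add(b)
        return ids


@dataclass
class ScoreMatrix:
    """Protein x GO-term prediction scores in [0, 1].

    Rows are proteins, columns are term ids; both id lists are unique and
    ordered.  ``values`` is an (n_proteins, n_terms) float array.
    """

    proteins: list[str]
    terms: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, t = len(self.proteins), len(self.terms)
        if self.values.shape != (n, t):
            raise ValidationError(
                f"score matrix shape {self.values.shape} does not match "
                f"{n} proteins x {t} terms"
            )
        if len(set(self.proteins)) != n:
            raise ValidationError("duplicate protein ids in score matrix")
        if len(set(self.terms)) != t:
            raise ValidationError("duplicate term ids in score matrix")
        if self.values.size and (
            not np.isfinite(self.values).all()
            or self.values.min() < 0.0
            or self.values.max() > 1.0
        ):
            raise ValidationError("scores must be finite and within [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, protein: str) -> np.ndarray:
        try:
            return self.values[self.proteins.index(protein)]
        except ValueError:
            raise MissingIdError(f"unknown protein id: {protein}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.proteins, columns=self.terms)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ScoreMatrix":
        return cls(
            proteins=[str(i) for i in frame.index],
            terms=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def reindex(self, proteins: list[str], terms: list[str]) -> "ScoreMatrix":
        """Return a copy with rows/columns reordered to the given id lists."""
        pidx = {p: i for i, p in enumerate(self.proteins)}
        tidx = {t: i for i, t in enumerate(self.terms)}
        try:
            rows = [pidx[p] for p in proteins]
            cols = [tidx[t] for t in terms]
        except KeyError as exc:
            raise MissingIdError(f"unknown id: {exc.args[0]}")
        return ScoreMatrix(list(proteins), list(terms), self.values[np.ix_(rows, cols)])
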