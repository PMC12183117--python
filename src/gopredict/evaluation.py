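"""CAFA-style evaluation: protein-centric Fmax, function-centric AUPR and
the Naive term-frequency baseline.

Fmax follows the CAFA protein-centric rule: at each threshold t on a 0.01
grid, precision is averaged over the proteins with at least one prediction
>= t (the "covered" set) while recall is averaged over all benchmark
proteins; Fmax is the maximum F1 over the grid.  AUPR is computed per GO
term as average precision and macro-averaged over terms with at least one
positive ("term-centric"); a micro mode pools all protein-term pairs into
one ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score

from .containers import ScoreMatrix
from .errors import ValidationError
from .ontology import AnnotationSet

logger = logging.getLogger(__name__)


@dataclass
class EvalResult:
    """Fmax with its attaining threshold, optional AUPR, and the full
    per-threshold (threshold, precision, recall, coverage) table."""

    fmax: float
    best_threshold: float
    table: np.ndarray  # columns: threshold, precision, recall, coverage
    aupr: float | None = None

    def summary(self) -> str:
        lines = [
            f"Fmax           {self.fmax:.4f}",
            f"best threshold {self.best_threshold:.2f}",
        ]
        if self.aupr is not None:
            lines.append(f"AUPR           {self.aupr:.4f}")
        return "\n".join(lines)


def _align(scores: ScoreMatrix, truth: AnnotationSet):
    """Binary truth matrix aligned to the evaluation protein set.

    Evaluation proteins are the truth proteins with a non-empty term set;
    score rows without truth are excluded (warned), truth proteins without
    a score row get all-zero predictions.  Columns are the score matrix's
    terms; true terms outside that vocabulary still count in each
    protein's recall denominator via ``extra_true``.
    """
    eval_proteins = sorted(p for p, ts in truth.annotations.items() if ts)
    if not eval_proteins:
        raise ValidationError("empty ground truth: no protein has any term")
    ignored = set(scores.proteins) - set(truth.annotations)
    if ignored:
        logger.warning(
            "%d scored proteins absent from ground truth are excluded",
            len(ignored),
        )
    term_index = {t: j for j, t in enumerate(scores.terms)}
    n, t = len(eval_proteins), len(scores.terms)
    s = np.zeros((n, t))
    y = np.zeros((n, t), dtype=bool)
    extra_true = np.zeros(n, dtype=int)
    row_of = {p: i for i, p in enumerate(scores.proteins)}
    for i, protein in enumerate(eval_proteins):
        if protein in row_of:
            s[i] = scores.values[row_of[protein]]
        for term in truth.annotations[protein]:
            j = term_index.get(term)
            if j is None:
                extra_true[i] += 1
            else:
                y[i, j] = True
    return eval_proteins, s, y, extra_true


def fmax(
    scores: ScoreMatrix, truth: AnnotationSet, step: float = 0.01
) -> EvalResult:
    """Protein-centric Fmax over the threshold grid {step, 2*step, ..., 1}.

    Assumes truth is ancestor-propagated with roots removed and scores are
    max-propagated.  On ties the smallest attaining threshold is reported.
    """
    _, s, y, extra_true = _align(scores, truth)
    return _fmax_core(s, y, extra_true, step)


def fmax_arrays(s: np.ndarray, y: np.ndarray, step: float = 0.01) -> EvalResult:
    """Fmax straight from aligned arrays: scores *s* and binary truth *y*
    of equal shape.  Rows with no true term are excluded from evaluation."""
    s = np.asarray(s, dtype=float)
    y = np.asarray(y, dtype=bool)
    if s.shape != y.shape:
        raise ValidationError(f"shape mismatch: {s.shape} vs {y.shape}")
    keep = y.any(axis=1)
    if not keep.any():
        raise ValidationError("empty ground truth: no protein has any term")
    s, y = s[keep], y[keep]
    return _fmax_core(s, y, np.zeros(s.shape[0], dtype=int), step)


def _fmax_core(
    s: np.ndarray, y: np.ndarray, extra_true: np.ndarray, step: float
) -> EvalResult:
    n_true = y.sum(axis=1) + extra_true  # >= 1 by construction
    thresholds = np.round(np.arange(step, 1.0 + step / 2, step), 10)
    rows = []
    best_f, best_t = 0.0, float(thresholds[0])
    n = s.shape[0]
    for t in thresholds:
        pred = s >= t
        n_pred = pred.sum(axis=1)
        tp = (pred & y).sum(axis=1)
        covered = n_pred > 0
        m = int(covered.sum())
        pr = float((tp[covered] / n_pred[covered]).mean()) if m else 0.0
        rc = float((tp / n_true).mean())  # averaged over ALL proteins
        f = 2 * pr * rc / (pr + rc) if (pr + rc) > 0 and m else 0.0
        rows.append((t, pr, rc, m / n))
        if f > best_f:
            best_f, best_t = f, float(t)
    return EvalResult(fmax=best_f, best_threshold=best_t, table=np.array(rows))


def aupr(scores: ScoreMatrix, truth: AnnotationSet, mode: str = "term-centric") -> float:
    """Function-centric AUPR.

    ``term-centric`` (default): average precision per term with >= 1
    positive, macro-averaged.  ``micro``: one average precision over all
    protein-term pairs.
    """
    if mode not in {"term-centric", "micro"}:
        raise ValueError(f"unknown AUPR mode: {mode!r}")
    _, s, y, _ = _align(scores, truth)
    if mode == "micro":
        if not y.any():
            raise ValidationError("no positive protein-term pair")
        return float(average_precision_score(y.ravel(), s.ravel()))
    eligible = np.flatnonzero(y.any(axis=0))
    if eligible.size == 0:
        raise ValidationError("no term with at least one positive")
    aps = [float(average_precision_score(y[:, j], s[:, j])) for j in eligible]
    return float(np.mean(aps))


def evaluate(
    scores: ScoreMatrix,
    truth: AnnotationSet,
    step: float = 0.01,
    aupr_mode: str = "term-centric",
) -> EvalResult:
    """Fmax and AUPR in one result."""
    result = fmax(scores, truth, step=step)
    result.aupr = aupr(scores, truth, mode=aupr_mode)
    return result


def naive_baseline(
    train_annots: AnnotationSet, target_proteins: list[str]
) -> ScoreMatrix:
    """The CAFA Naive predictor: every target protein receives, for each
    term, the term's relative annotation frequency in the training set."""
    n_train = len(train_annots.annotations)
    if n_train == 0:
        raise ValidationError("empty training annotation set")
    counts: dict[str, int] = {}
    for terms in train_annots.annotations.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    terms = sorted(counts)
    freq = np.array([counts[t] / n_train for t in terms])
    values = np.tile(freq, (len(target_proteins), 1))
    return ScoreMatrix(list(target_proteins), terms, values)
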