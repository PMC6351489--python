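"""Threshold-swept, micro-averaged Recall/Precision/Fmax evaluation.

For each threshold t, the predicted term set of lncRNA i is
P_i(t) = {terms with score >= t}; per-lncRNA TP/FP/FN counts are summed
over all evaluated lncRNAs *before* forming recall and precision
(micro-averaging, as the evaluation protocol prints it), and Fmax is the
maximum harmonic mean over the sweep. Only lncRNAs possessing at least one
true term enter the evaluation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .types import ValidationError

logger = logging.getLogger("mprnmf")


@dataclass
class EvaluationReport:
    thresholds: list[float]
    recalls: list[float]
    precisions: list[float]
    fmax: float
    best_t: float
    counts_at_best: dict[str, tuple[int, int, int]]
    n_correctly_annotated: int
    evaluated_lncs: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fmax": self.fmax,
            "best_threshold": self.best_t,
            "n_correctly_annotated": self.n_correctly_annotated,
            "curve": [
                {"threshold": t, "recall": r, "precision": p}
                for t, r, p in zip(self.thresholds, self.recalls, self.precisions)
            ],
        }


def confusion_counts(
    predicted: dict[str, set[str]],
    truth: dict[str, set[str]],
    universe: set[str],
) -> dict[str, tuple[int, int, int]]:
    """Per-lncRNA (TP, FP, FN) over an explicit term universe."""
    counts: dict[str, tuple[int, int, int]] = {}
    for lnc in truth:
        P = predicted.get(lnc, set())
        T = truth[lnc]
        stray = (P | T) - universe
        if stray:
            raise ValidationError(
                f"terms outside the universe for {lnc!r}: {sorted(stray)[:5]}"
            )
        tp = len(P & T)
        counts[lnc] = (tp, len(P) - tp, len(T) - tp)
    return counts


def recall_precision(
    counts: dict[str, tuple[int, int, int]]
) -> tuple[float, float]:
    """Micro-averaged recall and precision over the per-lncRNA counts.

    Degenerate denominators use total conventions so a full threshold sweep
    is always defined: precision is 1 when nothing is predicted, recall is
    0 when nothing is true.
    """
    if not counts:
        raise ValidationError("empty confusion-count collection")
    tp = sum(c[0] for c in counts.values())
    fp = sum(c[1] for c in counts.values())
    fn = sum(c[2] for c in counts.values())
    if tp + fn == 0:
        logger.debug("recall denominator zero; using convention recall=0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    if tp + fp == 0:
        logger.debug("precision denominator zero; using convention precision=1")
        precision = 1.0
    else:
        precision = tp / (tp + fp)
    return recall, precision


def fmax(
    scores: np.ndarray,
    truth: dict[str, set[str]],
    grid: list[float],
    term_ids: list[str],
    lnc_ids: list[str],
    universe: set[str] | None = None,
) -> EvaluationReport:
    """Sweep thresholds over a (terms x lncRNAs) score matrix.

    ``truth`` maps lncRNA id -> true term set; lncRNAs absent from ``truth``
    or with empty true sets are not evaluated. Ties in the maximizing
    threshold break toward the smallest t.
    """
    grid = list(grid)
    if not grid:
        raise ValidationError("threshold grid must be nonempty")
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(term_ids), len(lnc_ids)):
        raise ValidationError(
            f"score shape {scores.shape} inconsistent with "
            f"{len(term_ids)} terms x {len(lnc_ids)} lncRNAs"
        )
    universe = set(term_ids) if universe is None else universe
    eval_truth = {
        lnc: terms for lnc, terms in truth.items() if terms and lnc in set(lnc_ids)
    }
    if not eval_truth:
        raise ValidationError("no lncRNA with at least one true term to evaluate")
    col = {lnc: j for j, lnc in enumerate(lnc_ids)}
    terms_arr = np.asarray(term_ids)

    best = (-1.0, 0.0)  # (F, t)
    recalls, precisions = [], []
    best_counts: dict[str, tuple[int, int, int]] = {}
    for t in grid:
        predicted = {
            lnc: set(terms_arr[scores[:, col[lnc]] >= t]) for lnc in eval_truth
        }
        counts = confusion_counts(predicted, eval_truth, universe)
        r, p = recall_precision(counts)
        recalls.append(r)
        precisions.append(p)
        f = 0.0 if r + p == 0 else 2 * r * p / (r + p)
        if f > best[0]:
            best = (f, t)
            best_counts = counts
    n_correct = sum(1 for c in best_counts.values() if c[0] >= 1)
    return EvaluationReport(
        thresholds=grid,
        recalls=recalls,
        precisions=precisions,
        fmax=max(best[0], 0.0),
        best_t=best[1],
        counts_at_best=best_counts,
        n_correctly_annotated=n_correct,
        evaluated_lncs=sorted(eval_truth),
    )


def annotated_count(
    scores: np.ndarray,
    truth: dict[str, set[str]],
    t: float,
    term_ids: list[str],
    lnc_ids: list[str],
) -> int:
    """Number of lncRNAs with at least one true positive at threshold t."""
    scores = np.asarray(scores, dtype=float)
    terms_arr = np.asarray(term_ids)
    col = {lnc: j for j, lnc in enumerate(lnc_ids)}
    count = 0
    for lnc, T in truth.items():
        if not T or lnc not in col:
            continue
        predicted = set(terms_arr[scores[:, col[lnc]] >= t])
        if predicted & T:
            count += 1
    return count
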