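"""Evaluation statistics for stride/phase detection and length estimation.

Segment detection is scored by one-to-one matching of predicted against
labeled intervals (greedy, by descending temporal IoU), from which
precision, recall and F-score follow.  Temporal IoU uses the *spanning*
interval as the union -- for overlapping intervals this equals the set
union; for disjoint intervals the intersection is zero so the distinction
is moot for the ratio.  Length accuracy is scored by RMSE per stride and by
the relative error of the accumulated distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import GaitPhaseLabel, SampleInterval


def iou(a: SampleInterval, b: SampleInterval, union: str = "span") -> float:
    """Temporal intersection-over-union of two half-open intervals.

    ``union="span"`` (default) divides by ``max(end) - min(start)``;
    ``union="set"`` divides by the true set-union measure (differs from the
    span only when the intervals are disjoint).
    """
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    if union == "span":
        u = max(a.end, b.end) - min(a.start, b.start)
    elif union == "set":
        u = len(a) + len(b) - inter
    else:
        raise ValueError("union must be 'span' or 'set'")
    return inter / u if u > 0 else 0.0


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list = field(default_factory=list)  # (predicted, labeled) interval pairs

    @property
    def ious(self) -> list[float]:
        return [iou(p, t) for p, t in self.pairs]


def match_segments(
    predicted: Sequence[SampleInterval],
    labeled: Sequence[SampleInterval],
    min_iou: float = 0.0,
) -> MatchResult:
    """Greedy one-to-one matching by descending IoU.

    A pair counts as a true positive when its IoU exceeds ``min_iou`` (with
    the default 0.0, any strictly positive overlap qualifies).  Unmatched
    predictions are false positives; unmatched labels are false negatives.
    """
    cand = []
    for pi, p in enumerate(predicted):
        for ti, t in enumerate(labeled):
            v = iou(p, t)
            if v > min_iou:
                cand.append((v, pi, ti))
    cand.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    pairs = []
    for v, pi, ti in cand:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        pairs.append((predicted[pi], labeled[ti]))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(predicted) - tp, fn=len(labeled) - tp, pairs=pairs)


def f_score(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and their harmonic mean; all 0 when ``tp == 0``."""
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    if tp == 0:
        return 0.0, 0.0, 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return precision, recall, 2 * precision * recall / (precision + recall)


def rmse(y_ref: Sequence[float], y_pred: Sequence[float]) -> float:
    y_ref = np.asarray(y_ref, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_ref.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_ref.shape} vs {y_pred.shape}")
    return float(np.sqrt(np.mean((y_ref - y_pred) ** 2)))


def relative_error(distance: float, y_pred: Sequence[float]) -> float:
    """Relative error (%) of the accumulated predicted distance against the
    measured path length."""
    if distance == 0:
        raise ValueError("reference distance must be non-zero")
    return float((distance - float(np.sum(y_pred))) / distance * 100.0)


@dataclass
class PhaseReport:
    precision: float
    recall: float
    f_score: float
    mean_iou: float
    tp: int
    fp: int
    fn: int


@dataclass
class EvaluationReport:
    per_phase: dict  # phase name -> PhaseReport
    rmse: float | None = None
    relative_error_percent: float | None = None

    def to_dict(self) -> dict:
        d = {
            phase: {
                "precision": r.precision,
                "recall": r.recall,
                "f_score": r.f_score,
                "mean_iou": r.mean_iou,
                "tp": r.tp,
                "fp": r.fp,
                "fn": r.fn,
            }
            for phase, r in self.per_phase.items()
        }
        out: dict = {"per_phase": d}
        if self.rmse is not None:
            out["rmse"] = self.rmse
        if self.relative_error_percent is not None:
            out["relative_error_percent"] = self.relative_error_percent
        return out


def evaluate_phases(
    predicted: Sequence[GaitPhaseLabel],
    labeled: Sequence[GaitPhaseLabel],
    min_iou: float = 0.0,
) -> EvaluationReport:
    """Per-phase precision/recall/F and mean IoU over true-positive pairs."""
    phases = sorted({p.phase for p in labeled} | {p.phase for p in predicted})
    per_phase = {}
    for phase in phases:
        pred = [p.interval for p in predicted if p.phase == phase]
        truth = [p.interval for p in labeled if p.phase == phase]
        m = match_segments(pred, truth, min_iou=min_iou)
        precision, recall, f = f_score(m.tp, m.fp, m.fn)
        per_phase[phase] = PhaseReport(
            precision=precision,
            recall=recall,
            f_score=f,
            mean_iou=float(np.mean(m.ious)) if m.pairs else 0.0,
            tp=m.tp,
            fp=m.fp,
            fn=m.fn,
        )
    return EvaluationReport(per_phase=per_phase)
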