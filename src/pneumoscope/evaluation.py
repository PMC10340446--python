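"""Confusion counts, recall/precision/f1/f2 and report rendering.

The positive class is pneumonia in both training scenarios; the
anomaly-to-label mapping happens upstream in the classifier. f2 weights
recall four times as heavily as precision, reflecting that a missed
pneumonia (false negative) is the costliest error. Metrics with a zero
denominator are reported as undefined flags, never silently as zeros.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .classifier import AnomalyDecision


class AlignmentError(ValueError):
    pass


def _round2(x: float) -> float:
    """Round half-up to two decimals (report rendering only)."""
    return math.floor(x * 100 + 0.5) / 100


def confusion(decisions: Sequence[AnomalyDecision],
              truths: dict[str, str] | Sequence[str]
              ) -> tuple[int, int, int, int]:
    """(tp, fp, fn, tn) against true labels ("positive"/"negative").

    truths may be a source_id -> label mapping or a sequence aligned
    with the decisions.
    """
    if isinstance(truths, dict):
        missing = [d.source_id for d in decisions if d.source_id not in truths]
        if missing:
            raise AlignmentError(
                f"no truth label for source_id(s) {missing[:5]}")
        pairs = [(d.predicted_label, truths[d.source_id]) for d in decisions]
    else:
        if len(truths) != len(decisions):
            raise AlignmentError(
                f"{len(decisions)} decisions vs {len(truths)} truths")
        pairs = [(d.predicted_label, t) for d, t in zip(decisions, truths)]
    tp = fp = fn = tn = 0
    for pred, true in pairs:
        if true not in ("positive", "negative"):
            raise AlignmentError(f"invalid truth label {true!r}")
        if pred == "positive":
            if true == "positive":
                tp += 1
            else:
                fp += 1
        else:
            if true == "positive":
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def recall(tp: int, fn: int) -> float | None:
    """TP / (TP + FN), or None when undefined."""
    return tp / (tp + fn) if tp + fn > 0 else None


def precision(tp: int, fp: int) -> float | None:
    """TP / (TP + FP), or None when undefined."""
    return tp / (tp + fp) if tp + fp > 0 else None


def f_beta(recall_: float, precision_: float, beta_weight: float = 1.0
           ) -> float | None:
    """F-measure from recall and precision on a common scale.

    f1 = 2RP/(R+P); f2 = 5RP/(R+4P). Returns None when R = P = 0.
    Inputs may be proportions in [0,1] or percentages in [0,100], as
    long as both use the same scale.
    """
    if recall_ < 0 or precision_ < 0:
        raise ValueError("recall and precision must be nonnegative")
    b2 = beta_weight ** 2
    denom = recall_ + b2 * precision_
    if denom == 0:
        return None
    return (1 + b2) * recall_ * precision_ / denom


@dataclass
class EvaluationReport:
    """Confusion counts plus the four metrics as percentages (or None)."""

    model_tag: str
    scenario: str
    tp: int
    fp: int
    fn: int
    tn: int
    recall: float | None
    precision: float | None
    f1: float | None
    f2: float | None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        return {
            "model_tag": self.model_tag, "scenario": self.scenario,
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "recall": self.recall, "precision": self.precision,
            "f1": self.f1, "f2": self.f2,
        }


def evaluate(decisions: Sequence[AnomalyDecision],
             truths: dict[str, str] | Sequence[str],
             model_tag: str = "", scenario: str = "") -> EvaluationReport:
    """Full evaluation of a decision set, metrics as percentages."""
    tp, fp, fn, tn = confusion(decisions, truths)
    r = recall(tp, fn)
    p = precision(tp, fp)
    f1 = f2 = None
    if r is not None and p is not None and (r > 0 or p > 0):
        f1 = f_beta(r, p, 1)
        f2 = f_beta(r, p, 2)
    pct = lambda v: None if v is None else 100.0 * v
    return EvaluationReport(model_tag=model_tag, scenario=scenario,
                            tp=tp, fp=fp, fn=fn, tn=tn,
                            recall=pct(r), precision=pct(p),
                            f1=pct(f1), f2=pct(f2))


# -- rendering ------------------------------------------------------------

_COLUMNS = ("Recall", "Precision", "f1-Score", "f2-Score")
_FIELDS = ("recall", "precision", "f1", "f2")


def _cell(value: float | None) -> str:
    return "undefined" if value is None else f"{_round2(value):.2f}%"


def render_report(reports: Sequence[EvaluationReport]) -> str:
    """Aligned text table, one row per model; best value per metric
    column is flagged with a trailing ``*``."""
    if not reports:
        raise ValueError("nothing to render")
    best = {}
    for f in _FIELDS:
        vals = [getattr(r, f) for r in reports if getattr(r, f) is not None]
        best[f] = max(vals) if vals and len(reports) > 1 else None
    rows = []
    for rep in reports:
        cells = [rep.model_tag or "model"]
        for f in _FIELDS:
            v = getattr(rep, f)
            flag = "*" if best[f] is not None and v is not None \
                and _round2(v) == _round2(best[f]) else ""
            cells.append(_cell(v) + flag)
        rows.append(cells)
    header = ["Model", *_COLUMNS]
    widths = [max(len(header[i]), *(len(r[i]) for r in rows))
              for i in range(len(header))]
    fmt = "  ".join(f"{{:<{w}}}" for w in widths)
    lines = [fmt.format(*header), fmt.format(*("-" * w for w in widths))]
    lines += [fmt.format(*r) for r in rows]
    return "\n".join(lines)


def parse_report(text: str) -> list[dict[str, float | None]]:
    """Parse a render_report table back into metric dicts (two-decimal
    values, as rendered)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    out = []
    for ln in lines[2:]:
        parts = ln.split()
        vals = {}
        for f, raw in zip(_FIELDS, parts[-4:]):
            raw = raw.rstrip("*")
            vals[f] = None if raw == "undefined" else float(raw.rstrip("%"))
        out.append({"model_tag": " ".join(parts[:-4]), **vals})
    return out


def reports_to_json(reports: Sequence[EvaluationReport]) -> str:
    return json.dumps([r.to_dict() for r in reports], indent=2)


def reports_to_csv(reports: Iterable[EvaluationReport]) -> str:
    lines = ["model_tag,scenario,tp,fp,fn,tn,recall,precision,f1,f2"]
    for r in reports:
        vals = [r.model_tag, r.scenario, r.tp, r.fp, r.fn, r.tn,
                *(("" if getattr(r, f) is None else f"{getattr(r, f):.6f}")
                  for f in _FIELDS)]
        lines.append(",".join(str(v) for v in vals))
    return "\n".join(lines) + "\n"
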