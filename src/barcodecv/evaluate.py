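"""Multi-class evaluation of cross-validated taxonomic predictions.

Accuracy is the percentage of targets whose predicted taxon equals the
true one, with unassigned targets counted as not correct.  Per-class
precision P = TP/(TP+FP), recall R = TP/(TP+FN) and F = 2PR/(P+R) are
derived from the multi-class confusion counts.  Micro-averaged
precision is computed over the assigned rows only, micro recall over
all rows; when every query receives a prediction the micro metrics all
collapse to the accuracy (micro F1).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class Metrics:
    """Evaluation summary at one rank for one assignment method."""

    rank: str
    n_total: int
    n_correct: int
    n_wrong: int
    n_unassigned: int
    accuracy: float
    per_class: pd.DataFrame
    micro_precision: float
    micro_recall: float
    micro_f: float | None


def evaluate(rows: pd.DataFrame, rank: str) -> Metrics:
    """Compute :class:`Metrics` from a single-method results table."""
    if rows.empty:
        raise ValueError("rows must be non-empty")
    if rows["method"].nunique() > 1:
        raise ValueError("evaluate expects a single method; filter first")
    true = rows[f"true_{rank}"]
    pred = rows[f"{rank}_taxon"]
    assigned = pred.notna()
    correct = assigned & (pred == true)

    n_total = len(rows)
    n_correct = int(correct.sum())
    n_unassigned = int((~assigned).sum())
    n_wrong = n_total - n_correct - n_unassigned

    classes = sorted(set(true.dropna()) | set(pred.dropna()))
    records = []
    for cls in classes:
        tp = int((correct & (true == cls)).sum())
        fp = int((assigned & (pred == cls) & (true != cls)).sum())
        fn = int(((true == cls) & ~(correct & (true == cls))).sum())
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else None
        records.append({"taxon": cls, "tp": tp, "fp": fp, "fn": fn,
                        "precision": p, "recall": r, "f_score": f})
    per_class = pd.DataFrame(records, columns=["taxon", "tp", "fp", "fn",
                                               "precision", "recall", "f_score"])

    n_assigned = n_total - n_unassigned
    accuracy = 100.0 * n_correct / n_total
    micro_p = 100.0 * n_correct / n_assigned if n_assigned else 0.0
    micro_r = accuracy  # recall over all rows == accuracy by construction
    micro_f = (
        micro_p if micro_p == micro_r  # exact equality when nothing unassigned
        else 2 * micro_p * micro_r / (micro_p + micro_r) if micro_p + micro_r
        else None
    )
    return Metrics(
        rank=rank,
        n_total=n_total,
        n_correct=n_correct,
        n_wrong=n_wrong,
        n_unassigned=n_unassigned,
        accuracy=accuracy,
        per_class=per_class,
        micro_precision=micro_p,
        micro_recall=micro_r,
        micro_f=micro_f,
    )


def accuracy_by(rows: pd.DataFrame, rank: str, by: list[str]) -> pd.DataFrame:
    """Accuracy (%) at *rank* grouped by the given columns (e.g. method,
    origin); unassigned counts as not correct."""
    col = f"{rank}_correct"
    out = (
        rows.groupby(by, dropna=False)[col]
        .agg(n="size", accuracy="mean")
        .reset_index()
    )
    out["accuracy"] *= 100.0
    return out
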