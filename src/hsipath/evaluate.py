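"""Confusion-matrix metrics, ROC-AUC and per-patient aggregation.

Conventions: the tumor class is positive, so sensitivity is tumor
detection and specificity is non-tumor recognition.  Probabilities at or
above the decision threshold predict tumor.  A metric whose denominator
is empty (e.g. specificity for a patient with no non-tumor patches) is
``N.A.`` — represented as NaN — and aggregate rows average only the
defined entries, unweighted across patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .errors import ValidationError

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "metrics",
    "roc_auc",
    "aggregate",
    "per_patient_report",
    "MetricsReport",
]

DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(
    probabilities, labels, threshold: float = DEFAULT_THRESHOLD
) -> ConfusionCounts:
    """Tally thresholded predictions against binary labels (1 = tumor).

    Ties go to the positive class: ``p >= threshold`` predicts tumor.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if p.size == 0:
        raise ValidationError("cannot compute confusion counts on empty input")
    if p.shape != y.shape:
        raise ValidationError(f"length mismatch: {p.shape} scores vs {y.shape} labels")
    pred = p >= threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy); empty denominators give NaN.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    accuracy = (TN+TP)/(TN+TP+FP+FN).
    """
    sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else math.nan
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else math.nan
    acc = (c.tn + c.tp) / c.total if c.total else math.nan
    return sens, spec, acc


def roc_auc(probabilities, labels) -> float:
    """Area under the ROC curve; NaN when only one class is present.

    Equals the Mann-Whitney probability that a random tumor patch
    outscores a random non-tumor patch, ties counted one half.
    """
    y = np.asarray(labels).astype(int)
    if y.size == 0 or len(np.unique(y)) < 2:
        return math.nan
    return float(roc_auc_score(y, np.asarray(probabilities, dtype=float)))


def aggregate(values) -> tuple[float, float]:
    """(mean, sample sd) over the non-NaN entries; a single entry has sd 0."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return math.nan, math.nan
    if v.size == 1:
        return float(v[0]), 0.0
    return float(v.mean()), float(v.std(ddof=1))


def _round_half_away(x: float, decimals: int = 0) -> float:
    if math.isnan(x):
        return math.nan
    factor = 10**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass
class MetricsReport:
    """Per-patient metric rows plus their unweighted aggregate.

    ``frame`` columns: patient_id, auc, accuracy, sensitivity, specificity
    (percent), n_patches.  Raw unrounded values are kept; rounding is a
    display concern only (half away from zero, AUC to two decimals).
    """

    frame: pd.DataFrame

    METRIC_COLS = ("auc", "accuracy", "sensitivity", "specificity")

    def aggregate_rows(self) -> pd.DataFrame:
        stats = {col: aggregate(self.frame[col]) for col in self.METRIC_COLS}
        avg = {col: stats[col][0] for col in self.METRIC_COLS}
        std = {col: stats[col][1] for col in self.METRIC_COLS}
        avg.update(patient_id="Avg.", n_patches=int(self.frame["n_patches"].sum()))
        std.update(patient_id="Std.", n_patches=np.nan)
        return pd.DataFrame([avg, std])

    def summary(self) -> str:
        def fmt(row):
            cells = [f"{row['patient_id']:>6}"]
            auc = row["auc"]
            cells.append("  N.A." if math.isnan(auc) else f"{_round_half_away(auc, 2):6.2f}")
            for col in ("accuracy", "sensitivity", "specificity"):
                val = row[col]
                cells.append(
                    "  N.A." if math.isnan(val) else f"{_round_half_away(val):6.0f}"
                )
            return " ".join(cells)

        header = f"{'patient':>6} {'AUC':>6} {'acc%':>6} {'sens%':>6} {'spec%':>6}"
        body = [fmt(row) for _, row in self.frame.iterrows()]
        body += [fmt(row) for _, row in self.aggregate_rows().iterrows()]
        return "\n".join([header, *body])


def per_patient_report(
    probabilities,
    labels,
    patient_ids,
    excluded=None,
    threshold: float = DEFAULT_THRESHOLD,
) -> MetricsReport:
    """Build the per-patient test report from patch-level scores.

    ``excluded`` is an optional boolean mask of patches to drop before
    evaluation (manifest exclusion flags applied at evaluation time; the
    classifier is never retrained for this).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    pids = np.asarray(patient_ids, dtype=object)
    if excluded is not None:
        keep = ~np.asarray(excluded, dtype=bool)
        p, y, pids = p[keep], y[keep], pids[keep]
    rows = []
    for pid in sorted(set(pids.tolist())):
        m = pids == pid
        c = confusion_counts(p[m], y[m], threshold)
        sens, spec, acc = metrics(c)
        rows.append(
            {
                "patient_id": pid,
                "auc": roc_auc(p[m], y[m]),
                "accuracy": acc * 100 if not math.isnan(acc) else math.nan,
                "sensitivity": sens * 100 if not math.isnan(sens) else math.nan,
                "specificity": spec * 100 if not math.isnan(spec) else math.nan,
                "n_patches": int(m.sum()),
            }
        )
    return MetricsReport(frame=pd.DataFrame(rows))
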