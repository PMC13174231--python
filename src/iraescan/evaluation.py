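"""Multi-label evaluation: per-label and micro/macro P/R/S/F1 with NA conventions.

Each evaluation unit (a note or a patient) carries a set of positive labels;
the empty set is the explicit 'None' annotation and contributes a true negative
or false positive for every label. Per-label 2x2 counts give precision
(positive predictive value), recall (sensitivity), specificity, and F1. The
micro row pools counts across labels into one 2x2 table; the macro row is the
unweighted mean over labels, excluding NA entries per metric. A ratio is NA
exactly when its denominator is zero; F1 is 0 when TP=0 but errors exist, and
NA when TP=FP=FN=0 (a label absent from both gold and predictions).
Category-level evaluation projects both sides through the profile's
label→organ-category map (OR semantics) and then scores identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .vocab import SiteProfile, map_to_categories

MICRO_ROW = "micro avg"
MACRO_ROW = "macro avg"
METRIC_COLUMNS = ["P", "R", "S", "F1"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-label 2x2 counts over a fixed set of evaluation units."""

    counts: dict[str, tuple[int, int, int, int]]  # label -> (TP, FP, FN, TN)
    n_units: int

    def __post_init__(self) -> None:
        for label, (tp, fp, fn, tn) in self.counts.items():
            if min(tp, fp, fn, tn) < 0 or tp + fp + fn + tn != self.n_units:
                raise ValueError(
                    f"counts for {label!r} do not partition {self.n_units} units"
                )

    def pooled(self) -> tuple[int, int, int, int]:
        """Counts summed over labels — the micro-average 2x2 table."""
        arr = np.array(list(self.counts.values()), dtype=int)
        if arr.size == 0:
            return (0, 0, 0, 0)
        tp, fp, fn, tn = arr.sum(axis=0)
        return int(tp), int(fp), int(fn), int(tn)


def confusion_counts(
    pred: Mapping[str, Iterable[str]],
    gold: Mapping[str, Iterable[str]],
    labels: Iterable[str],
) -> ConfusionCounts:
    """2x2 counts per label from per-unit predicted and gold label sets.

    ``pred`` and ``gold`` must cover identical unit ids (notes or patients).
    """
    pred_ids, gold_ids = set(pred), set(gold)
    if pred_ids != gold_ids:
        missing = sorted(gold_ids - pred_ids)[:5]
        extra = sorted(pred_ids - gold_ids)[:5]
        raise ValueError(
            f"prediction/gold unit ids differ (missing from pred: {missing}, "
            f"extra in pred: {extra})"
        )
    labels = list(labels)
    pred_sets = {u: frozenset(v) for u, v in pred.items()}
    gold_sets = {u: frozenset(v) for u, v in gold.items()}
    counts: dict[str, tuple[int, int, int, int]] = {}
    for label in labels:
        tp = fp = fn = tn = 0
        for unit in pred_sets:
            p = label in pred_sets[unit]
            g = label in gold_sets[unit]
            if p and g:
                tp += 1
            elif p:
                fp += 1
            elif g:
                fn += 1
            else:
                tn += 1
        counts[label] = (tp, fp, fn, tn)
    return ConfusionCounts(counts=counts, n_units=len(pred_sets))


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def _row_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    p = _ratio(tp, tp + fp)
    r = _ratio(tp, tp + fn)
    s = _ratio(tn, tn + fp)
    if tp == 0 and fp == 0 and fn == 0:
        f1 = float("nan")
    elif tp == 0:
        f1 = 0.0
    else:
        f1 = 2 * p * r / (p + r)
    return {"P": p, "R": r, "S": s, "F1": f1}


def compute_metrics(counts: ConfusionCounts) -> pd.DataFrame:
    """MetricsTable: one row per label plus 'micro avg' and 'macro avg' rows.

    NA cells are NaN. The macro row averages only labels whose metric is
    defined; a metric undefined for every label stays NA in the macro row.
    """
    rows: dict[str, dict[str, float]] = {}
    for label, (tp, fp, fn, tn) in counts.counts.items():
        rows[label] = _row_metrics(tp, fp, fn, tn)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=METRIC_COLUMNS)

    micro = _row_metrics(*counts.pooled())
    macro = {
        col: (float(np.nanmean(v)) if not np.all(np.isnan(v)) else float("nan"))
        for col, v in (
            (c, table[c].to_numpy(dtype=float)) for c in METRIC_COLUMNS
        )
    } if len(table) else {c: float("nan") for c in METRIC_COLUMNS}
    table.loc[MICRO_ROW] = micro
    table.loc[MACRO_ROW] = macro
    return table


def evaluate_label_sets(
    pred: Mapping[str, Iterable[str]],
    gold: Mapping[str, Iterable[str]],
    labels: Iterable[str],
) -> pd.DataFrame:
    """Convenience: confusion counts then metrics in one call."""
    return compute_metrics(confusion_counts(pred, gold, labels))


def evaluate_at_category_level(
    pred: Mapping[str, Iterable[str]],
    gold: Mapping[str, Iterable[str]],
    profile: SiteProfile,
) -> pd.DataFrame:
    """Project both sides through the organ-category map, then score.

    A category is positive for a unit iff any of its member labels is — the OR
    semantics that makes within-category confusions (e.g. predicting colitis
    where gold says hepatitis) count as category-level agreement.
    """
    pred_cat = {u: map_to_categories(v, profile) for u, v in pred.items()}
    gold_cat = {u: map_to_categories(v, profile) for u, v in gold.items()}
    categories = sorted(
        {profile.category_of(lid) for lid in profile.label_ids}
    )
    return compute_metrics(confusion_counts(pred_cat, gold_cat, categories))


def micro_f1(counts: ConfusionCounts) -> float:
    """Micro-averaged F1 from the pooled 2x2 table (NaN if undefined)."""
    return _row_metrics(*counts.pooled())["F1"]
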