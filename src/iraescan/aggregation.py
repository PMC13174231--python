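"""Note-to-patient aggregation via a positive-note-count decision threshold.

A patient's notes are classified independently; the patient-level call for a
label is positive when at least ``k`` notes carry a positive call for it.
``k=1`` is plain logical OR over notes — the rule for corpora with one or a
handful of notes per patient. For note-rich corpora the threshold trades
precision against recall: raising ``k`` shrinks every predicted-positive set
(nesting), so per-label TP and FP are non-increasing in ``k``, micro-recall is
non-increasing, and micro-specificity non-decreasing. :func:`sweep_threshold`
scans ``k = 1..k_max``, scores each against patient-level gold, and reports the
``k`` maximizing micro-averaged F1 (smallest on ties).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import confusion_counts, _row_metrics
from .parsing import NotePrediction


@dataclass(frozen=True)
class AggregationPolicy:
    """Minimum number of irAE-positive notes for a patient-level positive."""

    k: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("decision threshold k must be >= 1")


@dataclass(frozen=True)
class PatientPrediction:
    patient_id: str
    positive_note_counts: dict[str, int]
    calls: dict[str, str]  # label_id -> "Yes" | "No"

    def positive_labels(self) -> frozenset[str]:
        return frozenset(lid for lid, v in self.calls.items() if v == "Yes")


@dataclass(frozen=True)
class ThresholdCurve:
    """Micro metrics per threshold value, and the F1-optimal threshold."""

    table: pd.DataFrame  # columns: k, micro_precision, micro_recall, micro_specificity, micro_f1
    k_best: int

    def micro_f1_at(self, k: int) -> float:
        row = self.table.loc[self.table["k"] == k]
        if row.empty:
            raise KeyError(f"threshold {k} outside the swept range")
        return float(row["micro_f1"].iloc[0])


def count_positive_notes(preds: Sequence[NotePrediction]) -> dict[str, int]:
    """Per-label count of notes called "Yes" for one patient."""
    patients = {p.patient_id for p in preds}
    if len(patients) > 1:
        raise ValueError(f"predictions span multiple patients: {sorted(patients)}")
    counts: dict[str, int] = {}
    for pred in preds:
        for lid, call in pred.calls.items():
            counts.setdefault(lid, 0)
            if call == "Yes":
                counts[lid] += 1
    return counts


def apply_threshold(
    patient_id: str,
    counts: Mapping[str, int],
    policy: AggregationPolicy,
) -> PatientPrediction:
    """Threshold per-label positive-note counts into a patient-level call."""
    calls = {
        lid: ("Yes" if n >= policy.k else "No") for lid, n in counts.items()
    }
    return PatientPrediction(
        patient_id=patient_id,
        positive_note_counts=dict(counts),
        calls=calls,
    )


def aggregate_predictions(
    preds: Iterable[NotePrediction],
    policy: AggregationPolicy,
    labels: Sequence[str],
) -> dict[str, PatientPrediction]:
    """Group note predictions by patient, count positives, and threshold."""
    by_patient: dict[str, list[NotePrediction]] = {}
    for pred in preds:
        by_patient.setdefault(pred.patient_id, []).append(pred)
    out: dict[str, PatientPrediction] = {}
    for pid, plist in by_patient.items():
        counts = count_positive_notes(plist)
        for lid in labels:
            counts.setdefault(lid, 0)
        out[pid] = apply_threshold(pid, counts, policy)
    return out


def patient_counts(
    preds: Iterable[NotePrediction], labels: Sequence[str]
) -> dict[str, dict[str, int]]:
    """Per-patient per-label positive-note counts (threshold-free view)."""
    by_patient: dict[str, list[NotePrediction]] = {}
    for pred in preds:
        by_patient.setdefault(pred.patient_id, []).append(pred)
    out: dict[str, dict[str, int]] = {}
    for pid, plist in by_patient.items():
        counts = count_positive_notes(plist)
        for lid in labels:
            counts.setdefault(lid, 0)
        out[pid] = counts
    return out


def sweep_threshold(
    counts_by_patient: Mapping[str, Mapping[str, int]],
    gold: Mapping[str, Iterable[str]],
    k_max: int | None = None,
    labels: Sequence[str] | None = None,
) -> ThresholdCurve:
    """Scan thresholds 1..k_max against patient-level gold labels.

    ``k_max`` defaults to the largest per-label positive-note count observed
    (at least 1); beyond it the curve is constant. ``k_best`` is the smallest
    threshold attaining the maximum micro-averaged F1.
    """
    if not counts_by_patient:
        raise ValueError("no patients to sweep")
    missing = set(counts_by_patient) - set(gold)
    if missing:
        raise ValueError(f"gold labels missing for patient(s): {sorted(missing)[:5]}")
    if labels is None:
        labels = sorted({lid for c in counts_by_patient.values() for lid in c})
    if k_max is None:
        k_max = max(
            (n for c in counts_by_patient.values() for n in c.values()), default=1
        )
        k_max = max(k_max, 1)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")

    gold_sets = {pid: frozenset(gold[pid]) for pid in counts_by_patient}
    rows = []
    for k in range(1, k_max + 1):
        pred_sets = {
            pid: frozenset(lid for lid, n in counts.items() if n >= k)
            for pid, counts in counts_by_patient.items()
        }
        cc = confusion_counts(pred_sets, gold_sets, labels)
        m = _row_metrics(*cc.pooled())
        rows.append(
            {
                "k": k,
                "micro_precision": m["P"],
                "micro_recall": m["R"],
                "micro_specificity": m["S"],
                "micro_f1": m["F1"],
            }
        )
    table = pd.DataFrame(rows)
    f1 = table["micro_f1"].to_numpy(dtype=float)
    f1_filled = np.where(np.isnan(f1), -np.inf, f1)
    k_best = int(table["k"].iloc[int(np.argmax(f1_filled))])
    return ThresholdCurve(table=table, k_best=k_best)
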