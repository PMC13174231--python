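"""File formats: notes JSONL, gold CSVs, exposures CSV, predictions JSONL.

One note per JSONL line (``patient_id``, ``note_id``, ``timestamp``,
``note_type``, ``text``); patient gold as CSV with semicolon-joined label ids
(empty field = the 'None' annotation); optional note-level gold in the same
shape keyed by note id; ICI exposures as CSV (patient, drug, first/last date).
All writers emit deterministic, diff-friendly text so identical runs produce
byte-identical artifacts.
"""

from __future__ import annotations

import csv
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .parsing import NotePrediction
from .simulate import ClinicalNote, PatientRecord


def write_notes_jsonl(records: Iterable[PatientRecord], path: str | Path) -> None:
    import json

    with open(path, "w") as fh:
        for rec in records:
            for note in rec.notes:
                fh.write(
                    json.dumps(
                        {
                            "patient_id": note.patient_id,
                            "note_id": note.note_id,
                            "timestamp": note.timestamp.isoformat(),
                            "note_type": note.note_type,
                            "text": note.text,
                        }
                    )
                    + "\n"
                )


def read_notes_jsonl(path: str | Path) -> list[ClinicalNote]:
    import json

    notes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            notes.append(
                ClinicalNote(
                    note_id=d["note_id"],
                    patient_id=d["patient_id"],
                    timestamp=date.fromisoformat(d["timestamp"]),
                    note_type=d.get("note_type", ""),
                    text=d["text"],
                )
            )
    return notes


def write_gold_patients_csv(
    gold: Mapping[str, Iterable[str]], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "labels"])
        for pid in sorted(gold):
            w.writerow([pid, ";".join(sorted(gold[pid]))])


def read_gold_csv(path: str | Path, id_column: str = "patient_id") -> dict[str, frozenset[str]]:
    out: dict[str, frozenset[str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            labels = row["labels"].strip()
            out[row[id_column]] = (
                frozenset(labels.split(";")) if labels else frozenset()
            )
    return out


def write_gold_notes_csv(
    records: Iterable[PatientRecord], path: str | Path
) -> None:
    """Note-level gold for every note, empty field for notes without irAEs."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["note_id", "patient_id", "labels"])
        for rec in records:
            for note in rec.notes:
                w.writerow(
                    [
                        note.note_id,
                        note.patient_id,
                        ";".join(sorted(rec.note_gold(note.note_id))),
                    ]
                )


def write_exposures_csv(records: Iterable[PatientRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "drug", "first_date", "last_date"])
        for rec in records:
            for drug, first, last in rec.ici_exposures:
                w.writerow([rec.patient_id, drug, first.isoformat(), last.isoformat()])


def write_predictions_jsonl(
    preds: Iterable[NotePrediction], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for pred in preds:
            fh.write(pred.to_json() + "\n")


def read_predictions_jsonl(path: str | Path) -> list[NotePrediction]:
    preds = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                preds.append(NotePrediction.from_json(line))
    return preds


def write_patient_calls_csv(
    calls: Mapping[str, Mapping[str, str]], labels: Sequence[str], path: str | Path
) -> None:
    """Patient-level calls, one row per patient, one Yes/No column per label."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", *labels])
        for pid in sorted(calls):
            w.writerow([pid, *(calls[pid].get(lid, "No") for lid in labels)])
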