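"""End-to-end orchestration: simulate → classify → parse → aggregate → evaluate.

:func:`run_pipeline` executes the whole chain on a simulated (or loaded)
corpus, persists every intermediate artifact in the documented formats, and
writes a run manifest sufficient to re-execute the run bit-identically with
the mock backend. Stages can also be re-run from persisted predictions without
re-invoking a backend: aggregation and evaluation read the predictions JSONL.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import io as _io
from .aggregation import (
    AggregationPolicy,
    ThresholdCurve,
    aggregate_predictions,
    patient_counts,
    sweep_threshold,
)
from .backend import Backend, BackendRequest, classify, get_backend
from .evaluation import evaluate_at_category_level, evaluate_label_sets
from .parsing import NotePrediction, parse_response
from .prompting import render_prompt
from .simulate import (
    ClinicalNote,
    PatientRecord,
    SimConfig,
    filter_notes_by_window,
    generate_corpus,
)
from .vocab import SiteProfile, load_site_profile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunManifest:
    profile_id: str
    profile_hash: str
    backend_id: str
    seed: int
    k: int
    k_best: int | None
    n_patients: int
    n_notes: int
    outputs: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "profile_id": self.profile_id,
                "profile_hash": self.profile_hash,
                "backend_id": self.backend_id,
                "seed": self.seed,
                "k": self.k,
                "k_best": self.k_best,
                "n_patients": self.n_patients,
                "n_notes": self.n_notes,
                "outputs": self.outputs,
            },
            indent=2,
        )


def profile_hash(profile: SiteProfile) -> str:
    canon = json.dumps(profile.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def classify_notes(
    notes: Sequence[ClinicalNote],
    profile: SiteProfile,
    backend: Backend,
) -> list[NotePrediction]:
    """Render, classify, and parse every note; never aborts mid-corpus."""
    preds = []
    status_tally: dict[str, int] = {}
    for note in notes:
        request = BackendRequest(
            prompt_text=render_prompt(note.text, profile).text,
            label_ids=profile.label_ids,
        )
        raw = classify(request, backend)
        pred = parse_response(
            raw, profile.label_ids, note_id=note.note_id, patient_id=note.patient_id
        )
        status_tally[pred.parse_status] = status_tally.get(pred.parse_status, 0) + 1
        preds.append(pred)
    logger.info("classified %d notes; parse status: %s", len(notes), status_tally)
    return preds


def evaluate_patient_level(
    preds: Sequence[NotePrediction],
    gold_patient: Mapping[str, frozenset[str]],
    profile: SiteProfile,
    k: int | None = None,
    sweep: bool = True,
) -> tuple[dict, pd.DataFrame, pd.DataFrame, ThresholdCurve | None]:
    """Aggregate note predictions and score against patient-level gold.

    Returns (patient calls, label metrics, category metrics, curve-or-None).
    With ``sweep`` the threshold is the micro-F1-optimal one; otherwise ``k``
    (default 1, the OR rule).
    """
    labels = profile.label_ids
    counts = patient_counts(preds, labels)
    curve = None
    if sweep:
        curve = sweep_threshold(counts, gold_patient, labels=labels)
        k = curve.k_best
    policy = AggregationPolicy(k=k or 1)
    patients = aggregate_predictions(preds, policy, labels)
    pred_sets = {pid: p.positive_labels() for pid, p in patients.items()}
    gold_sets = {pid: frozenset(gold_patient[pid]) for pid in pred_sets}
    label_metrics = evaluate_label_sets(pred_sets, gold_sets, labels)
    category_metrics = evaluate_at_category_level(pred_sets, gold_sets, profile)
    calls = {pid: p.calls for pid, p in patients.items()}
    return calls, label_metrics, category_metrics, curve


def evaluate_note_level(
    preds: Sequence[NotePrediction],
    gold_notes: Mapping[str, frozenset[str]],
    profile: SiteProfile,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score note-level calls against explicit note-level gold."""
    pred_sets = {p.note_id: p.positive_labels() for p in preds}
    gold_sets = {nid: frozenset(gold_notes.get(nid, frozenset())) for nid in pred_sets}
    label_metrics = evaluate_label_sets(pred_sets, gold_sets, profile.label_ids)
    category_metrics = evaluate_at_category_level(pred_sets, gold_sets, profile)
    return label_metrics, category_metrics


def run_pipeline(
    out_dir: str | Path,
    profile: SiteProfile | str | Path,
    sim_config: SimConfig | None = None,
    corpus_path: str | Path | None = None,
    gold_path: str | Path | None = None,
    note_gold_path: str | Path | None = None,
    backend_name: str = "mock",
    k: int | None = None,
    sweep: bool = True,
    months_after: int = 6,
) -> RunManifest:
    """Execute all stages and persist every artifact under ``out_dir``.

    Either ``sim_config`` (simulate a corpus) or ``corpus_path`` + ``gold_path``
    (load one) must be given. Note-level evaluation runs only when note-level
    gold exists; otherwise it is skipped with a logged notice.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not isinstance(profile, SiteProfile):
        profile = load_site_profile(profile)

    gold_notes: dict[str, frozenset[str]] | None = None
    if sim_config is not None:
        records = generate_corpus(sim_config, profile)
        records = [filter_notes_by_window(r, months_after) for r in records]
        notes = [n for r in records for n in r.notes]
        gold_patient = {r.patient_id: r.gold_patient for r in records}
        gold_notes = {n.note_id: r.note_gold(n.note_id) for r in records for n in r.notes}
        _io.write_notes_jsonl(records, out / "notes.jsonl")
        _io.write_gold_patients_csv(gold_patient, out / "gold_patients.csv")
        _io.write_gold_notes_csv(records, out / "gold_notes.csv")
        _io.write_exposures_csv(records, out / "exposures.csv")
        seed = sim_config.seed
    elif corpus_path is not None and gold_path is not None:
        notes = _io.read_notes_jsonl(corpus_path)
        gold_patient = _io.read_gold_csv(gold_path)
        if note_gold_path is not None:
            gold_notes = _io.read_gold_csv(note_gold_path, id_column="note_id")
        seed = 0
    else:
        raise ValueError("provide either sim_config or corpus_path + gold_path")

    backend = get_backend(backend_name, profile)
    preds = classify_notes(notes, profile, backend)
    _io.write_predictions_jsonl(preds, out / "predictions.jsonl")

    calls, label_metrics, category_metrics, curve = evaluate_patient_level(
        preds, gold_patient, profile, k=k, sweep=sweep
    )
    _io.write_patient_calls_csv(calls, profile.label_ids, out / "patient_calls.csv")
    label_metrics.to_csv(out / "patient_metrics_labels.csv", index_label="label")
    category_metrics.to_csv(out / "patient_metrics_categories.csv", index_label="category")
    k_best = None
    if curve is not None:
        curve.table.to_csv(out / "threshold_curve.csv", index=False)
        k_best = curve.k_best

    if gold_notes is not None:
        nl_labels, nl_cats = evaluate_note_level(preds, gold_notes, profile)
        nl_labels.to_csv(out / "note_metrics_labels.csv", index_label="label")
        nl_cats.to_csv(out / "note_metrics_categories.csv", index_label="category")
    else:
        logger.info("no note-level gold provided; note-level evaluation skipped")

    outputs = {p.name: str(p) for p in sorted(out.iterdir()) if p.is_file()}
    manifest = RunManifest(
        profile_id=profile.site_id,
        profile_hash=profile_hash(profile),
        backend_id=backend.backend_id,
        seed=seed,
        k=k_best if k_best is not None else (k or 1),
        k_best=k_best,
        n_patients=len(gold_patient),
        n_notes=len(notes),
        outputs=outputs,
    )
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
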