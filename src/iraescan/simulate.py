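"""Synthetic patient-note corpora with known ground truth.

The generator emulates the structure of an annotated irAE corpus: each patient
has a set of ICI exposures, a handful of timestamped notes, and a gold label
set drawn per-label from configured prevalences. Every gold label is realized
as at least one positive-causal mention sentence ("Colitis attributed to
nivolumab; corticosteroids initiated."); non-gold labels may receive confounder
mentions — negated, hypothetical, or attributed to a non-ICI etiology — drawn
from the configured regime mixture, plus neutral distractor sentences. Because
confounders attach only to non-gold labels, ground truth stays unambiguous and
a pipeline that handles assertion and causation correctly recovers the gold
labels exactly.

Also hosts the corpus time-window filter: notes are retained from the first
day of ICI exposure through a configurable number of calendar months after the
last administration, both bounds inclusive, with end-of-month clamping for
month arithmetic.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from importlib import resources
from typing import Mapping

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .vocab import SiteProfile

REGIMES = ("positive_causal", "negated", "hypothetical", "alt_cause")

_NOTE_TYPES = ("progress", "consult", "discharge summary")


@dataclass(frozen=True)
class ClinicalNote:
    note_id: str
    patient_id: str
    timestamp: date
    note_type: str
    text: str


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    ici_exposures: tuple[tuple[str, date, date], ...]  # (drug, first, last)
    notes: tuple[ClinicalNote, ...]
    gold_patient: frozenset[str]
    gold_notes: dict[str, frozenset[str]] = field(default_factory=dict)

    def note_gold(self, note_id: str) -> frozenset[str]:
        """Gold labels of one note; notes without positive mentions are empty."""
        return self.gold_notes.get(note_id, frozenset())


class SimConfig(BaseModel):
    """Study conditions for one synthetic corpus.

    ``prevalence`` may be a single probability applied to every label or a
    per-label mapping. ``regime_mixture`` governs mentions of non-gold labels:
    one regime is drawn per (patient, non-gold label); a ``positive_causal``
    draw plants nothing (a positive mention of a non-gold label would corrupt
    the ground truth), so the positive weight is the probability a non-gold
    label stays silent. ``distractor_rate`` is the expected number of neutral
    filler sentences per note (Poisson).
    """

    model_config = ConfigDict(frozen=True)

    n_patients: int = 100
    notes_per_patient: tuple[int, int] = (3, 8)
    prevalence: float | dict[str, float] = 0.15
    regime_mixture: dict[str, float] = {
        "positive_causal": 0.55,
        "negated": 0.20,
        "hypothetical": 0.15,
        "alt_cause": 0.10,
    }
    synonym_use_prob: float = 0.3
    distractor_rate: float = 2.0
    seed: int = 0

    @field_validator("n_patients")
    @classmethod
    def _patients(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_patients must be >= 1")
        return v

    @field_validator("notes_per_patient")
    @classmethod
    def _notes_range(cls, v: tuple[int, int]) -> tuple[int, int]:
        lo, hi = v
        if lo < 0 or hi < lo:
            raise ValueError("notes_per_patient must be 0 <= min <= max")
        return v

    @field_validator("synonym_use_prob", "distractor_rate")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("rates/probabilities must be non-negative")
        return v

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if set(self.regime_mixture) != set(REGIMES):
            raise ValueError(f"regime_mixture must have exactly the keys {REGIMES}")
        total = sum(self.regime_mixture.values())
        if abs(total - 1.0) > 1e-9 or min(self.regime_mixture.values()) < 0:
            raise ValueError("regime_mixture probabilities must be >= 0 and sum to 1")
        prevs = (
            self.prevalence.values()
            if isinstance(self.prevalence, dict)
            else [self.prevalence]
        )
        if any(p < 0 or p > 1 for p in prevs):
            raise ValueError("prevalences must lie in [0, 1]")
        if self.synonym_use_prob > 1:
            raise ValueError("synonym_use_prob must lie in [0, 1]")
        return self

    def prevalence_for(self, label_id: str) -> float:
        if isinstance(self.prevalence, dict):
            return self.prevalence.get(label_id, 0.0)
        return self.prevalence


def load_sentence_templates(path: str | None = None) -> dict[str, list[str]]:
    """Mention/confounder/distractor sentence templates (bundled by default)."""
    if path is None:
        text = (resources.files("iraescan") / "templates" / "sentences.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    data = yaml.safe_load(text)
    required = set(REGIMES) | {"agents", "distractor", "opening"}
    missing = required - set(data)
    if missing:
        raise ValueError(f"sentence template file lacks section(s): {sorted(missing)}")
    return data


def _capitalize(sentence: str) -> str:
    return sentence[0].upper() + sentence[1:] if sentence else sentence


def generate_corpus(
    config: SimConfig,
    profile: SiteProfile,
    templates: Mapping[str, list[str]] | None = None,
) -> list[PatientRecord]:
    """Generate a corpus of :class:`PatientRecord` with note-level ground truth.

    Deterministic given ``config.seed``: the same configuration and profile
    always produce an identical corpus, sentence for sentence.
    """
    if templates is None:
        templates = load_sentence_templates()
    lo, hi = config.notes_per_patient
    max_prev = max(config.prevalence_for(lid) for lid in profile.label_ids)
    if lo < 1 and max_prev > 0:
        raise ValueError(
            "notes_per_patient allows 0 notes while label prevalence is nonzero; "
            "gold labels could not be realized as mentions"
        )
    rng = np.random.default_rng(config.seed)
    regime_probs = np.array([config.regime_mixture[r] for r in REGIMES])

    def pick(seq: list[str]) -> str:
        return seq[int(rng.integers(len(seq)))]

    def surface_form(label_id: str) -> str:
        lab = profile.get_label(label_id)
        if lab.synset and rng.random() < config.synonym_use_prob:
            return lab.synset[int(rng.integers(len(lab.synset)))]
        return lab.display_name

    records: list[PatientRecord] = []
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        drug = profile.ici_drugs[int(rng.integers(len(profile.ici_drugs)))]
        first = date(2020, 1, 1) + timedelta(days=int(rng.integers(0, 181)))
        last = first + timedelta(days=int(rng.integers(0, 121)))
        n_notes = int(rng.integers(lo, hi + 1))

        offsets = sorted(
            int(rng.integers(0, (last - first).days + 150)) for _ in range(n_notes)
        )
        notes_meta = [
            (
                f"{pid}-N{j:03d}",
                first + timedelta(days=offsets[j]),
                _NOTE_TYPES[int(rng.integers(len(_NOTE_TYPES)))],
            )
            for j in range(n_notes)
        ]
        # sentences planted per note, beyond the opening line
        planted: list[list[str]] = [[] for _ in range(n_notes)]
        gold_note_sets: list[set[str]] = [set() for _ in range(n_notes)]

        gold: set[str] = set()
        for lid in profile.label_ids:
            if rng.random() < config.prevalence_for(lid):
                gold.add(lid)
                n_mention = 1 + int(rng.binomial(n_notes - 1, 0.25)) if n_notes > 1 else 1
                idxs = rng.choice(n_notes, size=n_mention, replace=False)
                for j in sorted(int(x) for x in idxs):
                    sent = pick(templates["positive_causal"]).format(
                        term=surface_form(lid), ici=drug
                    )
                    planted[j].append(_capitalize(sent))
                    gold_note_sets[j].add(lid)
            else:
                regime = REGIMES[int(rng.choice(len(REGIMES), p=regime_probs))]
                if regime != "positive_causal" and n_notes > 0:
                    j = int(rng.integers(n_notes))
                    fields = {"term": surface_form(lid), "ici": drug}
                    if regime == "alt_cause":
                        fields["agent"] = pick(templates["agents"])
                    sent = pick(templates[regime]).format(**fields)
                    planted[j].append(_capitalize(sent))

        notes: list[ClinicalNote] = []
        gold_notes: dict[str, frozenset[str]] = {}
        for j, (nid, ts, ntype) in enumerate(notes_meta):
            body = planted[j] + [
                pick(templates["distractor"])
                for _ in range(int(rng.poisson(config.distractor_rate)))
            ]
            order = rng.permutation(len(body)) if body else []
            sentences = [
                _capitalize(pick(templates["opening"]).format(note_type=ntype, ici=drug))
            ] + [body[int(o)] for o in order]
            notes.append(
                ClinicalNote(
                    note_id=nid,
                    patient_id=pid,
                    timestamp=ts,
                    note_type=ntype,
                    text=" ".join(sentences),
                )
            )
            if gold_note_sets[j]:
                gold_notes[nid] = frozenset(gold_note_sets[j])

        records.append(
            PatientRecord(
                patient_id=pid,
                ici_exposures=((drug, first, last),),
                notes=tuple(notes),
                gold_patient=frozenset(gold),
                gold_notes=gold_notes,
            )
        )
    return records


def add_months(d: date, months: int) -> date:
    """Calendar-month arithmetic with end-of-month clamping."""
    month_index = d.month - 1 + months
    year = d.year + month_index // 12
    month = month_index % 12 + 1
    day = min(d.day, calendar.monthrange(year, month)[1])
    return date(year, month, day)


def filter_notes_by_window(record: PatientRecord, months_after: int = 6) -> PatientRecord:
    """Retain notes between the first ICI exposure date and ``months_after``
    calendar months after the last administration, both bounds inclusive."""
    if not record.ici_exposures:
        raise ValueError(f"patient {record.patient_id} has no ICI exposures")
    first = min(exp[1] for exp in record.ici_exposures)
    last = max(exp[2] for exp in record.ici_exposures)
    end = add_months(last, months_after)
    kept = tuple(n for n in record.notes if first <= n.timestamp <= end)
    kept_ids = {n.note_id for n in kept}
    return replace(
        record,
        notes=kept,
        gold_notes={k: v for k, v in record.gold_notes.items() if k in kept_ids},
    )
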