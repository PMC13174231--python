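"""Parse raw backend text into validated note-level predictions.

The backend is asked for a single JSON object with one "Yes"/"No" field per
label, but real model output strays: prose around the JSON, missing or extra
keys, off-vocabulary values, refusals. Parsing never raises — every outcome is
encoded in ``parse_status`` (``clean`` / ``repaired`` / ``failed``) so batch
runs over a corpus never abort mid-way, and the calls key-set always equals the
expected label list exactly regardless of input garbage. Failures and repairs
default to "No": the conservative direction for extractors already biased
toward over-predicting positives.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

from .backend import RawResponse

logger = logging.getLogger(__name__)

CLEAN = "clean"
REPAIRED = "repaired"
FAILED = "failed"


@dataclass(frozen=True)
class NotePrediction:
    """Per-note multi-label calls plus parse provenance."""

    note_id: str
    patient_id: str
    calls: dict[str, str]  # label_id -> "Yes" | "No"
    parse_status: str
    diagnostics: tuple[str, ...] = field(default=())

    def positive_labels(self) -> frozenset[str]:
        return frozenset(lid for lid, v in self.calls.items() if v == "Yes")

    def to_json(self) -> str:
        return json.dumps(
            {
                "note_id": self.note_id,
                "patient_id": self.patient_id,
                "calls": self.calls,
                "parse_status": self.parse_status,
                "diagnostics": list(self.diagnostics),
            }
        )

    @classmethod
    def from_json(cls, line: str) -> "NotePrediction":
        d = json.loads(line)
        return cls(
            note_id=d["note_id"],
            patient_id=d["patient_id"],
            calls=dict(d["calls"]),
            parse_status=d["parse_status"],
            diagnostics=tuple(d.get("diagnostics", ())),
        )


def _normalize_value(value: object) -> str | None:
    """Map a JSON value to "Yes"/"No", or None if off-vocabulary."""
    if isinstance(value, str):
        low = value.strip().lower()
        if low == "yes":
            return "Yes"
        if low == "no":
            return "No"
    return None


def _extract_json_object(text: str) -> dict | None:
    """Best-effort extraction of a JSON object from surrounding prose."""
    start, end = text.find("{"), text.rfind("}")
    if start == -1 or end <= start:
        return None
    try:
        obj = json.loads(text[start : end + 1])
    except json.JSONDecodeError:
        return None
    return obj if isinstance(obj, dict) else None


def parse_response(
    raw: RawResponse,
    expected_labels: Sequence[str],
    note_id: str = "",
    patient_id: str = "",
) -> NotePrediction:
    """Turn raw backend text into a :class:`NotePrediction`.

    ``clean``: the text is exactly one JSON object with exactly the expected
    keys and case-insensitive "Yes"/"No" values. ``repaired``: a JSON object
    was extracted from prose, missing keys were defaulted to "No", extra keys
    dropped, or off-vocabulary values mapped to "No". ``failed``: no usable
    JSON (including transport failure) — all calls "No", with diagnostics.
    """
    expected = list(expected_labels)
    all_no = {lid: "No" for lid in expected}

    if not raw.ok:
        return NotePrediction(
            note_id,
            patient_id,
            all_no,
            FAILED,
            (f"backend failure: {raw.error or 'unknown'}",),
        )

    diagnostics: list[str] = []
    obj: dict | None = None
    extracted = False
    try:
        candidate = json.loads(raw.text)
        if isinstance(candidate, dict):
            obj = candidate
    except json.JSONDecodeError:
        pass
    if obj is None:
        obj = _extract_json_object(raw.text)
        if obj is not None:
            extracted = True
            diagnostics.append("JSON object extracted from surrounding prose")

    if obj is None:
        diagnostics.append("no JSON object found in backend output")
        logger.warning("parse failed for note %s: %s", note_id, diagnostics[-1])
        return NotePrediction(note_id, patient_id, all_no, FAILED, tuple(diagnostics))

    repaired = extracted
    calls: dict[str, str] = {}
    for lid in expected:
        if lid in obj:
            value = _normalize_value(obj[lid])
            if value is None:
                diagnostics.append(
                    f"off-vocabulary value {obj[lid]!r} for {lid!r} mapped to 'No'"
                )
                repaired = True
                value = "No"
            calls[lid] = value
        else:
            diagnostics.append(f"missing key {lid!r} defaulted to 'No'")
            repaired = True
            calls[lid] = "No"
    extra = set(obj) - set(expected)
    if extra:
        diagnostics.append(f"unexpected key(s) dropped: {sorted(extra)}")
        logger.warning("note %s: unexpected keys %s dropped", note_id, sorted(extra))
        repaired = True

    status = REPAIRED if repaired else CLEAN
    return NotePrediction(note_id, patient_id, calls, status, tuple(diagnostics))
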