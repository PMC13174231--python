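"""Zero-shot prompt rendering.

One prompt covers one clinical note and queries every irAE label of the site
profile as an independent binary question. Each query is augmented with the
label's synset so terminology variants are named explicitly, and the model is
instructed to answer with a single JSON object holding one "Yes"/"No" field per
label. Rendering is a pure function of (note text, profile, template): the same
inputs always produce a byte-identical prompt, which — together with temperature
0 decoding at the backend — makes runs reproducible.

The note body is wrapped between ``<<<NOTE`` / ``NOTE>>>`` sentinels. The
sentinels let audit tooling (and the deterministic mock backend) recover the
note text from a flattened prompt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .vocab import IrAELabel, SiteProfile

logger = logging.getLogger(__name__)

NOTE_OPEN = "<<<NOTE"
NOTE_CLOSE = "NOTE>>>"

#: Default cap on note length, in characters, before tail-first truncation.
DEFAULT_MAX_NOTE_CHARS = 48_000


def default_template() -> str:
    """The bundled prompt template (note placed before the queries)."""
    return (resources.files("iraescan") / "templates" / "prompt_default.txt").read_text()


@dataclass(frozen=True)
class PromptSpec:
    """A rendered prompt: preamble, per-label queries, output directive, note."""

    preamble: str
    queries: tuple[str, ...]
    output_instruction: str
    note_text: str
    text: str  # the flattened prompt actually sent to a backend


def render_query(label: IrAELabel) -> str:
    """Render the binary query sentence for one irAE label.

    The synset appears parenthesized after the display name, comma-separated in
    synset order; the parenthetical is omitted entirely for an empty synset.
    """
    if label.synset:
        subject = f"{label.display_name} ({', '.join(label.synset)})"
    else:
        subject = label.display_name
    return (
        f"Output 'Yes' if the patient has experienced {subject} because of "
        "exposure to one or more immune checkpoint inhibitors. "
        "Otherwise, output 'No'."
    )


def render_output_instruction(profile: SiteProfile) -> str:
    keys = ", ".join(f'"{lid}"' for lid in profile.label_ids)
    return (
        "Return your answers as a single JSON object with exactly one field per "
        f"adverse event, using the keys {keys}. Every value must be either "
        '"Yes" or "No". Output only the JSON object.'
    )


def render_prompt(
    note_text: str,
    profile: SiteProfile,
    template: str | None = None,
    max_note_chars: int = DEFAULT_MAX_NOTE_CHARS,
) -> PromptSpec:
    """Render the full zero-shot prompt for one note under one site profile.

    Notes longer than ``max_note_chars`` are truncated tail-first (the head of
    the note is kept) with a logged warning.
    """
    if not profile.labels:
        raise ValueError("cannot render a prompt from a profile with no labels")
    if not note_text or not note_text.strip():
        raise ValueError("cannot render a prompt for an empty note")
    if template is None:
        template = default_template()
    if len(note_text) > max_note_chars:
        logger.warning(
            "note of %d chars exceeds budget %d; truncating tail",
            len(note_text),
            max_note_chars,
        )
        note_text = note_text[:max_note_chars]

    ici_list = ", ".join(profile.ici_drugs)
    queries = tuple(render_query(lab) for lab in profile.labels)
    output_instruction = render_output_instruction(profile)
    text = template.format(
        ici_list=ici_list,
        note_text=note_text,
        queries="\n".join(queries),
        output_instruction=output_instruction,
    )
    preamble = text.split(NOTE_OPEN, 1)[0].strip()
    return PromptSpec(
        preamble=preamble,
        queries=queries,
        output_instruction=output_instruction,
        note_text=note_text,
        text=text,
    )


def extract_note_text(prompt_text: str) -> str | None:
    """Recover the note body from a flattened prompt, or None if unmarked."""
    if NOTE_OPEN not in prompt_text or NOTE_CLOSE not in prompt_text:
        return None
    after = prompt_text.split(NOTE_OPEN, 1)[1]
    body = after.split(NOTE_CLOSE, 1)[0]
    return body.strip("\n")


def dump_prompt(note_text: str, profile: SiteProfile, path: str | Path) -> None:
    """Audit helper: write the rendered prompt for one note to a file."""
    Path(path).write_text(render_prompt(note_text, profile).text)
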