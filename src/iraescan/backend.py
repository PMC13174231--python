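"""Classification backends.

A backend receives a flattened prompt and returns raw text that the parsing
stage turns into per-label calls. Two backends are provided behind one
contract:

* :class:`MockBackend` — a deterministic rule-based classifier. It recovers the
  note body from the prompt, matches label surface forms on word boundaries,
  and applies assertion/causation rules mirroring the failure taxonomy of
  clinical-text extraction: a mention is suppressed when a negation or
  hypothetical cue governs it, or when the nearest etiology marker attributes
  it to a non-ICI agent (e.g. "colitis secondary to infection"). It is the
  testable stand-in for a language model and the oracle for the synthetic
  corpus — a pure function of (note text, profile, rules).
* :class:`OpenAICompatibleBackend` — a thin adapter for any chat-completions
  HTTP endpoint, always decoding at temperature 0. Credentials come from the
  environment; transport failures are retried twice and then reported as
  ``ok=False``, never raised past the contract boundary.
"""

from __future__ import annotations

import json
import logging
import os
import re
import time
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from typing import Protocol, Sequence

from .prompting import extract_note_text
from .vocab import SiteProfile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BackendRequest:
    """One classification request: prompt text plus the expected output keys."""

    prompt_text: str
    label_ids: tuple[str, ...]
    decoding_temperature: float = 0.0

    def __post_init__(self) -> None:
        if self.decoding_temperature < 0:
            raise ValueError("decoding temperature must be non-negative")


@dataclass(frozen=True)
class RawResponse:
    text: str
    backend_id: str
    ok: bool
    error: str | None = None


@dataclass(frozen=True)
class CueRules:
    """Assertion and causation cues for the rule backend.

    ``window`` is the maximum token distance at which a negation/hypothetical
    cue, or an agent phrase following an etiology marker, governs a mention.
    All matching is case-insensitive on word-token sequences, so multi-word
    phrases match contiguously and hyphenation is immaterial.
    """

    negation_cues: tuple[str, ...] = (
        "no evidence of",
        "no signs of",
        "denies",
        "denied",
        "without",
        "ruled out",
        "negative for",
    )
    hypothetical_cues: tuple[str, ...] = (
        "risk of",
        "risks of",
        "monitor for",
        "watch for",
        "concern for",
        "possible",
        "in case of",
    )
    # Markers taking an agent phrase; suppression depends on what the agent is.
    alt_cause_markers: tuple[str, ...] = ("secondary to", "due to")
    causal_markers: tuple[str, ...] = ("attributed to", "caused by", "induced by")
    # Causal markers that need no agent: they assert immune mediation directly.
    agentless_causal_markers: tuple[str, ...] = ("immune mediated", "immune related")
    # Lexicon of non-ICI etiologies; an agent phrase containing one suppresses.
    non_ici_agents: tuple[str, ...] = (
        "infection",
        "chemotherapy",
        "radiation",
        "alcohol",
        "viral illness",
        "statin",
        "sepsis",
        "nsaid",
    )
    window: int = 10

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("cue window must be >= 1")
        for name in ("negation_cues", "hypothetical_cues", "alt_cause_markers", "causal_markers"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")


_TOKEN_RE = re.compile(r"[a-z0-9]+(?:'[a-z0-9]+)?")
_SENT_SPLIT_RE = re.compile(r"(?<=[.!?])\s+")


def tokenize(text: str) -> list[str]:
    """Lowercase word tokens; punctuation (incl. hyphens) splits tokens."""
    return _TOKEN_RE.findall(text.lower())


def split_sentences(text: str) -> list[str]:
    """Naive sentence split on terminal punctuation followed by whitespace.

    Clinical abbreviations may cause false splits; segmentation fidelity is not
    this backend's subject, and the cue rules are local enough to tolerate it.
    """
    return [s for s in _SENT_SPLIT_RE.split(text) if s.strip()]


def _find_phrase(tokens: Sequence[str], phrase_tokens: Sequence[str]) -> list[int]:
    """Start indices where ``phrase_tokens`` occurs contiguously in ``tokens``."""
    n, m = len(tokens), len(phrase_tokens)
    if m == 0 or m > n:
        return []
    return [i for i in range(n - m + 1) if list(tokens[i : i + m]) == list(phrase_tokens)]


def _phrase_spans(tokens: Sequence[str], phrases: Sequence[str]) -> list[tuple[int, int]]:
    """(start, end) token spans of every occurrence of every phrase."""
    spans: list[tuple[int, int]] = []
    for phrase in phrases:
        ptoks = tokenize(phrase)
        for start in _find_phrase(tokens, ptoks):
            spans.append((start, start + len(ptoks)))
    return spans


def _resolve_marker(
    tokens: Sequence[str],
    span: tuple[int, int],
    agentless: bool,
    rules: CueRules,
    ici_drugs: Sequence[str],
) -> str:
    """Classify the attribution a marker makes: 'ici' or 'alt'.

    Agentless immune-mediation markers attribute to the ICI class directly.
    Otherwise the agent phrase is the token window following the marker: an ICI
    drug name means the attribution stands; a recognized non-ICI agent means it
    is an alternative etiology; an unresolved agent leaves the mention standing
    (the conservative direction for a recall-oriented extractor).
    """
    if agentless:
        return "ici"
    start = span[1]
    window_toks = tokens[start : start + rules.window]
    for drug in ici_drugs:
        if _find_phrase(window_toks, tokenize(drug)):
            return "ici"
    for agent in rules.non_ici_agents:
        if _find_phrase(window_toks, tokenize(agent)):
            return "alt"
    return "ici"


def mock_annotate(
    note_text: str,
    profile: SiteProfile,
    rules: CueRules | None = None,
) -> dict[str, str]:
    """Rule-based note annotation: map each label_id to "Yes"/"No".

    A label is "Yes" iff some surface form (display name or synset term)
    matches on word boundaries in a sentence where (a) no negation or
    hypothetical cue ends within ``rules.window`` tokens before the match, and
    (b) the sentence's nearest etiology marker, if any, attributes the event to
    an ICI drug or asserts immune mediation rather than naming a non-ICI agent.
    An empty note yields all "No".
    """
    if rules is None:
        rules = CueRules()
    calls = {lid: "No" for lid in profile.label_ids}
    if not note_text or not note_text.strip():
        return calls

    for sentence in split_sentences(note_text):
        tokens = tokenize(sentence)
        if not tokens:
            continue
        cue_ends = [
            end
            for _, end in _phrase_spans(
                tokens, rules.negation_cues + rules.hypothetical_cues
            )
        ]
        markers: list[tuple[tuple[int, int], bool]] = [
            (span, False)
            for span in _phrase_spans(
                tokens, rules.alt_cause_markers + rules.causal_markers
            )
        ] + [
            (span, True)
            for span in _phrase_spans(tokens, rules.agentless_causal_markers)
        ]

        for label in profile.labels:
            if calls[label.label_id] == "Yes":
                continue
            for term in label.surface_forms:
                hit = False
                for start in _find_phrase(tokens, tokenize(term)):
                    if any(0 <= start - end < rules.window for end in cue_ends):
                        continue  # governed by a negation/hypothetical cue
                    if markers:
                        span, agentless = min(
                            markers, key=lambda m: abs(m[0][0] - start)
                        )
                        verdict = _resolve_marker(
                            tokens, span, agentless, rules, profile.ici_drugs
                        )
                        if verdict == "alt":
                            continue  # attributed to a non-ICI etiology
                    hit = True
                    break
                if hit:
                    calls[label.label_id] = "Yes"
                    break
    return calls


class Backend(Protocol):
    backend_id: str

    def classify(self, request: BackendRequest) -> RawResponse: ...


@dataclass
class MockBackend:
    """Deterministic rule backend: extracts the note from the prompt and
    answers every label with :func:`mock_annotate`, as clean JSON."""

    profile: SiteProfile
    rules: CueRules = field(default_factory=CueRules)
    backend_id: str = "mock"

    def classify(self, request: BackendRequest) -> RawResponse:
        note = extract_note_text(request.prompt_text)
        if note is None:
            return RawResponse(
                text="",
                backend_id=self.backend_id,
                ok=False,
                error="prompt lacks note sentinels; cannot recover note text",
            )
        calls = mock_annotate(note, self.profile, self.rules)
        ordered = {lid: calls.get(lid, "No") for lid in request.label_ids}
        return RawResponse(text=json.dumps(ordered), backend_id=self.backend_id, ok=True)


@dataclass
class OpenAICompatibleBackend:
    """Adapter for an OpenAI-compatible chat-completions endpoint.

    Configuration comes from arguments or the environment
    (``IRAESCAN_API_BASE``, ``IRAESCAN_API_KEY``, ``IRAESCAN_MODEL``); nothing
    is hard-coded. Temperature is pinned to the request's value (0 for
    replication runs). Transient transport failures are retried twice with
    backoff before reporting ``ok=False``.
    """

    api_base: str | None = None
    api_key: str | None = None
    model: str | None = None
    timeout: float = 60.0
    max_retries: int = 2
    backend_id: str = "openai-compatible"

    def __post_init__(self) -> None:
        self.api_base = self.api_base or os.environ.get("IRAESCAN_API_BASE")
        self.api_key = self.api_key or os.environ.get("IRAESCAN_API_KEY")
        self.model = self.model or os.environ.get("IRAESCAN_MODEL")

    def classify(self, request: BackendRequest) -> RawResponse:
        if not self.api_base or not self.model:
            return RawResponse(
                text="",
                backend_id=self.backend_id,
                ok=False,
                error="remote backend not configured (endpoint/model missing)",
            )
        payload = json.dumps(
            {
                "model": self.model,
                "temperature": request.decoding_temperature,
                "messages": [{"role": "user", "content": request.prompt_text}],
            }
        ).encode()
        headers = {"Content-Type": "application/json"}
        if self.api_key:
            headers["Authorization"] = f"Bearer {self.api_key}"
        url = self.api_base.rstrip("/") + "/chat/completions"
        last_err = "unknown transport failure"
        for attempt in range(self.max_retries + 1):
            try:
                req = urllib.request.Request(url, data=payload, headers=headers)
                with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                    body = json.loads(resp.read().decode())
                text = body["choices"][0]["message"]["content"]
                return RawResponse(text=text, backend_id=self.backend_id, ok=True)
            except (urllib.error.URLError, OSError, KeyError, json.JSONDecodeError, ValueError) as exc:
                last_err = f"{type(exc).__name__}: {exc}"
                if attempt < self.max_retries:
                    time.sleep(0.5 * 2**attempt)
        return RawResponse(text="", backend_id=self.backend_id, ok=False, error=last_err)


def classify(request: BackendRequest, backend: Backend) -> RawResponse:
    """Contract boundary: never raises; failures become ``ok=False`` responses."""
    try:
        return backend.classify(request)
    except Exception as exc:  # noqa: BLE001 — batch runs must not abort mid-corpus
        logger.error("backend %s raised: %s", getattr(backend, "backend_id", "?"), exc)
        return RawResponse(
            text="",
            backend_id=getattr(backend, "backend_id", "unknown"),
            ok=False,
            error=f"{type(exc).__name__}: {exc}",
        )


def get_backend(name: str, profile: SiteProfile, rules: CueRules | None = None) -> Backend:
    """Backend factory by name: ``mock`` or ``openai-compatible``."""
    if name == "mock":
        return MockBackend(profile=profile, rules=rules or CueRules())
    if name == "openai-compatible":
        return OpenAICompatibleBackend()
    raise ValueError(f"unknown backend {name!r}")
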