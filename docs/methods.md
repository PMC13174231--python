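# Methods

## Problem and model

Immune checkpoint inhibitors (ICIs — anti-PD-1/PD-L1 and anti-CTLA-4
antibodies such as nivolumab, pembrolizumab, atezolizumab, ipilimumab) cause
immune-related adverse events (irAEs) in a large fraction of treated patients,
across organ systems. irAEs are poorly captured by structured codes; the
causal link between drug and toxicity lives in free-text notes. `iraescan`
frames extraction as **multi-label classification**: each unit (a note, or a
patient after aggregation) carries any subset of a site-specific label set,
including the empty set ("None"). Labels are queried independently, one binary
question per label per note, so any combination can be returned.

Two properties separate this task from named-entity recognition:

* **Assertion status.** A mention may be negated, hypothetical ("risk of
  pneumonitis"), or about a possibility rather than an event.
* **Causal attribution.** Even a positively asserted event only counts when it
  is attributable to the ICI exposure, not to infection, chemotherapy,
  radiation, or another etiology.

## Site profiles and prompts

A `SiteProfile` fixes the label list, per-label synonym sets ("synsets"), the
ICI drug list, and a label→category map into a closed set of ten organ-level
categories (Cardiovascular, Dermatologic, Endocrine, Gastrointestinal,
Haematological, Musculoskeletal and Rheumatologic, Neurologic, Other,
Pulmonary, Renal). Institutions differ in label granularity — the bundled
`vumc` profile keeps colitis and diarrhoea separate where `ucsf` merges them
under one colitis label whose synset carries both terms — and the profile file
is the single artifact that makes a run reproducible. Labels missing from the
category map fall back to "Other" with a warning rather than being dropped,
which would silently corrupt pooled counts. The bundled profiles reconstruct
labels from published summaries; full institutional synset inventories are
site-internal, so synsets here are illustrative package choices.

The prompt places the note (between explicit sentinels) before the queries,
one query per label in profile order:

> Output 'Yes' if the patient has experienced *display-name* (*synset terms,
> comma-separated*) because of exposure to one or more immune checkpoint
> inhibitors. Otherwise, output 'No'.

with a directive to answer as one JSON object with one "Yes"/"No" field per
label. Rendering is pure: identical inputs yield byte-identical prompts. Notes
beyond a character budget (default 48,000 characters) are truncated tail-first
with a logged warning; the head of a clinical note is where context
concentrates. The template is a plain text file, auditable and overridable;
`iraescan render-prompt` dumps the exact prompt for any note.

## The rule backend

The deterministic backend is an original design: a transparent oracle aligned
with the assertion/causation failure taxonomy, not an emulation of any
language model. For each sentence (split naively on terminal punctuation —
clinical abbreviations may cause false splits, accepted because segmentation
fidelity is not the subject here), label surface forms are matched
case-insensitively on word-token boundaries, multi-word terms as contiguous
token sequences. A match is suppressed when:

1. a **negation or hypothetical cue** ("no evidence of", "denies", "risk of",
   "monitor for", …) ends within `window` tokens (default 10) before the
   match, within the sentence; or
2. the sentence's **nearest etiology marker** ("attributed to", "caused by",
   "secondary to", "due to", …) resolves to a recognized **non-ICI agent**
   (infection, chemotherapy, radiation, alcohol, …). Markers resolving to an
   ICI drug, agentless immune-mediation markers ("immune-mediated"), and
   markers with an unresolved agent leave the mention standing — the latter
   mirroring the over-prediction bias direction reported for recall-oriented
   extractors.

A plain positive mention with no etiology marker counts as positive. Adding a
synset term can only add candidate mentions, so it never flips a label from
Yes to No (monotonicity). All cue lists and the window are configurable
(`CueRules`).

The optional `openai-compatible` adapter posts the prompt to a
chat-completions endpoint at temperature 0 (deterministic decoding for binary
outputs), retries transient transport failures twice with backoff, and reports
`ok=False` rather than raising; credentials come from the environment.

## Parsing

Backend text is parsed into exactly the profile's label set regardless of
input: prose-wrapped JSON is extracted between the outermost braces, missing
keys default to "No", extra keys are dropped, off-vocabulary values map to
"No" — all recorded in `parse_status` (`clean`/`repaired`/`failed`) and
per-note diagnostics. Defaulting to "No" is deliberate: repair must not add
positives to a system already biased toward them. Failures never raise, so a
corpus run always completes.

## Aggregation and the decision threshold

Patient-level calls threshold the per-label count of positive notes at
`k ≥ 1`; `k=1` is logical OR (the natural rule when patients have one or few
notes). Predicted-positive sets are nested in `k`, hence per-label TP and FP
are non-increasing, micro-recall non-increasing and micro-specificity
non-decreasing — laws the tests verify by exhaustive re-thresholding.
`sweep_threshold` scans `k = 1..k_max` (default: the largest observed count,
beyond which the curve is constant) and picks the micro-F1 argmax, smallest
`k` on ties (favours recall). Selecting `k` on the evaluation corpus is
optimistic by design — it characterises the threshold's effect rather than
estimating generalisation; per-label thresholds and probabilistic aggregation
are out of scope.

## Evaluation

Per-label 2×2 counts over units give P = TP/(TP+FP), R = TP/(TP+FN),
S = TN/(TN+FP), F1 = 2PR/(P+R). Conventions for degenerate denominators: a
ratio is NA exactly when its denominator is 0; F1 is NA when TP=FP=FN=0 (label
absent on both sides) and 0 when TP=0 with errors present. The micro row pools
counts into one table; the macro row averages per metric over labels with
defined values (NA-exclusion is the only reading consistent with printing NA
cells alongside finite macro rows, and is stated here so outputs are
interpretable). Category-level evaluation projects both predictions and gold
through the category map — a category is positive iff any member label is —
then scores identically; within-category confusions therefore vanish at
category level, which the tests demonstrate constructively rather than
asserting as a universal ordering. Note-level evaluation requires explicit
note-level gold; patient-level annotations are never down-propagated to notes.

## Synthetic corpora

The generator emulates an annotated cohort's *structure*, not clinical
language. Defaults (one corpus = study conditions, chosen once): 100 patients,
3–8 notes per patient, per-label prevalence 0.15, mention-regime mixture
{positive-causal 0.55, negated 0.20, hypothetical 0.15, alternative-etiology
0.10}, synonym-use probability 0.3, two distractor sentences per note in
expectation (Poisson). Prevalence and note counts are in the range of
published irAE cohorts with curated note sets; the mixture makes positive
assertions the commonest regime while keeping all three confounder classes
present.

Per patient: gold labels are independent per-label Bernoulli draws; each gold
label is planted as a positive-causal sentence in ≥1 note (1 plus a
Binomial(n−1, 0.25) extra-note count, so threshold sweeps see counts above 1).
For each non-gold label one regime is drawn from the mixture; a
positive-causal draw plants nothing (a positive mention of a non-gold label
would corrupt the ground truth), otherwise a confounder sentence of the drawn
regime is planted. Confounder templates keep the governing cue *before* the
mention, matching the backend's cue scope, and alternative-etiology sentences
always name a non-ICI agent. Sentence templates live in a YAML data file so
regimes can be extended without code changes. `gold_notes` records exactly the
notes carrying positive-causal mentions, so the union over notes equals the
patient's gold set by construction.

The default `demo` profile keeps every label's surface forms disjoint from
every other label's, so each planted mention is attributable to exactly one
label. Timestamps fall inside the exposure window by default; the window
filter itself retains notes from the first ICI exposure date through
`months_after` (default 6) calendar months after the last administration,
**both bounds inclusive**, with month arithmetic clamped to month ends
(Aug 31 + 1 month = Sep 30).

Because generator and rule backend are aligned by construction, a
confounder-free corpus is recovered *exactly* (micro-F1 = 1.0 end-to-end), and
under the default mixture the rule backend still scores 1.0 — the confounder
regimes it models are precisely those it resolves. Passing these checks
validates the pipeline's bookkeeping (prompt → classify → parse → aggregate →
evaluate), the metric definitions, and the threshold laws. It does **not**
estimate performance on real clinical text, which has unmodelled phenomena:
paraphrase beyond synsets, cross-sentence causality, co-reference, list/table
formatting, misspellings, and true events missed by annotators. Real-backend
evaluation requires annotated notes and the remote adapter.

## Numerical and design choices

* Tie-break at equal micro-F1: smallest `k`. Deterministic and
  recall-favouring.
* Cue window 10 tokens, within-sentence scope; configurable.
* Unresolved etiology agents do not suppress (see above); only recognized
  non-ICI agents do.
* Problem sizes in tests and the acceptance script (200 patients, 5 labels,
  3–8 notes) are the package's chosen verification scale: large enough that
  every label and regime appears many times, small enough to iterate quickly.
* Randomness: a single integer seed drives one `numpy` Generator per corpus;
  identical seeds give byte-identical corpora, predictions, and CSVs.

## Limitations

The rule backend shares its vocabulary of cues with the generator, so
closed-loop scores are upper bounds by construction — that is their purpose as
oracles, and why they say nothing about language-model accuracy. The
sentence splitter is deliberately naive. Synset induction, MedDRA/ontology
integration, few-shot prompting, and probabilistic patient-level outputs are
explicitly out of scope.
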