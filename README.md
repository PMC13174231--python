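# iraescan

Multi-label identification of **immune-related adverse events (irAEs)** in
unstructured clinical notes of patients on **immune checkpoint inhibitor
(ICI)** therapy — with note-to-patient aggregation via a decision threshold and
per-label / per-organ-category evaluation.

## Who this is for

Pharmacovigilance and clinical-informatics teams who need to find which irAEs
(colitis, pneumonitis, rash, hepatitis, hypothyroidism, …) a patient
experienced *because of* ICI exposure, from free-text notes. The hard part is
not spotting the words: a mention may be negated ("no evidence of colitis"),
hypothetical ("discussed the risk of pneumonitis"), or positively asserted but
attributed to something other than the ICI ("rash secondary to recent
infection"). Only positively asserted, ICI-attributable events count.

## What it does

1. **Site vocabulary** (`vocab`): a YAML *site profile* holds the irAE label
   list, per-label synonym sets ("synsets"), the ICI drug list, and a mapping
   from labels to ten fixed organ categories. Three example profiles mirror
   common institutional conventions (e.g. colitis and diarrhoea as separate
   labels vs. merged under one label whose synset carries both terms).
2. **Prompting** (`prompting`): renders one zero-shot prompt per note, with one
   synset-augmented binary query per label —
   *"Output 'Yes' if the patient has experienced neuropathy (neurotox,
   neurotoxicity) because of exposure to one or more immune checkpoint
   inhibitors. Otherwise, output 'No'."* — and a JSON output directive.
3. **Backends** (`backend`): a deterministic **rule-based backend** that
   resolves negation, hypothetical framing, and etiology attribution with
   configurable cue lists (the testable stand-in for a language model), plus an
   optional adapter for any OpenAI-compatible endpoint at temperature 0.
4. **Parsing** (`parsing`): turns raw backend text into validated per-note
   calls; prose-wrapped JSON is repaired, missing keys default to "No",
   refusals are flagged — a batch run never aborts mid-corpus.
5. **Aggregation** (`aggregation`): a patient is positive for a label when at
   least *k* notes are; `k=1` is logical OR. `sweep_threshold` scans *k* and
   reports the micro-F1-optimal threshold.
6. **Evaluation** (`evaluation`): per-label precision (PPV), recall
   (sensitivity), specificity and F1, with pooled micro and NA-excluding macro
   rows, at note, patient, and organ-category level (categories score as OR
   over member labels).
7. **Synthetic corpora** (`simulate`): generates patient records with known
   ground truth — positive-causal mentions for gold labels, confounder
   mentions (negated / hypothetical / alternative-etiology) for non-gold
   labels — plus the exposure time-window filter (first ICI day through six
   calendar months after the last dose, inclusive).

## Worked example

```bash
iraescan run --profile demo --n-patients 50 --seed 7 --out-dir out/
```

simulates 50 patients, classifies every note with the rule backend, sweeps the
decision threshold, and writes metrics. The manifest printed at the end
includes:

```
"backend_id": "mock",
"seed": 7,
"k": 1,
"k_best": 1,
"n_patients": 50,
"n_notes": 286
```

`out/patient_metrics_labels.csv` then holds one row per label plus the
averages (this corpus is noise-free for the rule backend, so scores are 1.0;
`NA` marks a ratio whose denominator is zero — e.g. precision for a label
never predicted):

```
label,P,R,S,F1
colitis,1.0,1.0,1.0,1.0
...
micro avg,1.0,1.0,1.0,1.0
macro avg,1.0,1.0,1.0,1.0
```

and `out/threshold_curve.csv` records micro precision/recall/specificity/F1
for every threshold value, with `k_best` the smallest argmax of micro-F1.

The same stages are available piecewise (`iraescan simulate`, `classify`,
`aggregate`, `evaluate`, `render-prompt` for prompt auditing), all reading and
writing plain JSONL/CSV so any stage can be re-run from persisted artifacts.

As a library:

```python
from iraescan import SimConfig, load_builtin_profile, generate_corpus
from iraescan.backend import get_backend
from iraescan.pipeline import classify_notes, evaluate_patient_level

profile = load_builtin_profile("demo")
records = generate_corpus(SimConfig(n_patients=100, seed=0), profile)
notes = [n for r in records for n in r.notes]
preds = classify_notes(notes, profile, get_backend("mock", profile))
gold = {r.patient_id: r.gold_patient for r in records}
calls, metrics, categories, curve = evaluate_patient_level(preds, gold, profile)
print(metrics.loc["micro avg"])       # P 1.0  R 1.0  S 1.0  F1 1.0
print("optimal threshold:", curve.k_best)
```

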