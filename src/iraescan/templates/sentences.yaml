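# Sentence templates for the synthetic corpus generator. Placeholders:
#   {term}  - a label surface form (display name or synset term)
#   {ici}   - an ICI drug from the profile
#   {agent} - a non-ICI etiology phrase (alt_cause only)
#   {note_type} - the note type (opening only)
# Confounder templates keep the governing cue BEFORE the mention so the
# generator and the rule backend stay aligned on assertion scope.
positive_causal:
  - "{term} attributed to {ici}; corticosteroids initiated."
  - "The patient developed {term} caused by {ici}."
  - "Immune-mediated {term} in the setting of {ici} therapy."
negated:
  - "No evidence of {term} on today's exam."
  - "The patient denies {term} at this time."
  - "Imaging was negative for {term}."
hypothetical:
  - "Discussed the risk of {term} prior to continuing therapy."
  - "We will monitor for {term} during treatment."
alt_cause:
  - "{term} secondary to {agent}."
  - "{term} due to {agent}, unrelated to immunotherapy."
agents:
  - "recent infection"
  - "chemotherapy"
  - "radiation therapy"
  - "alcohol use"
  - "a viral illness"
distractor:
  - "Vital signs stable and afebrile today."
  - "Continue current medications as prescribed."
  - "Patient tolerating treatment well overall."
  - "Laboratory results reviewed and unremarkable."
  - "Follow-up appointment scheduled in three weeks."
  - "Performance status unchanged since last visit."
opening:
  - "Oncology {note_type} note during {ici} treatment."
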