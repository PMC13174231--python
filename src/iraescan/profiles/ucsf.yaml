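# Example hospital-admission site profile: coarser labels, with colitis and
# diarrhoea merged under a single colitis label whose synset carries both terms.
site_id: UCSF
labels:
  - {label_id: colitis, display_name: colitis, synset: [colitis, diarrhoea]}
  - {label_id: hepatitis, display_name: hepatitis, synset: [liver inflammation, transaminitis]}
  - {label_id: pneumonitis, display_name: pneumonitis, synset: [lung inflammation]}
  - {label_id: rash, display_name: rash, synset: [dermatitis]}
  - {label_id: stevens_johnson_syndrome, display_name: Stevens-Johnson syndrome, synset: [SJS]}
  - {label_id: guillain_barre, display_name: Guillain-Barre, synset: [GBS, ascending paralysis]}
  - {label_id: hypothyroidism, display_name: hypothyroidism, synset: [underactive thyroid]}
  - {label_id: adrenal_insufficiency, display_name: adrenal insufficiency, synset: []}
  - {label_id: myocarditis, display_name: myocarditis, synset: [heart inflammation]}
  - {label_id: arthritis, display_name: arthritis, synset: [inflammatory arthritis]}
  - {label_id: fever, display_name: fever, synset: [pyrexia]}
ici_drugs: [atezolizumab, avelumab, durvalumab, ipilimumab, nivolumab, pembrolizumab]
category_map:
  colitis: Gastrointestinal
  hepatitis: Gastrointestinal
  pneumonitis: Pulmonary
  rash: Dermatologic
  stevens_johnson_syndrome: Dermatologic
  guillain_barre: Neurologic
  hypothyroidism: Endocrine
  adrenal_insufficiency: Endocrine
  myocarditis: Cardiovascular
  arthritis: Musculoskeletal and Rheumatologic
  fever: Other
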