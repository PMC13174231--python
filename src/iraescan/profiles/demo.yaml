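# Default profile for synthetic corpora. Labels and synsets are mutually
# disjoint (no surface form of one label appears under another), so a planted
# mention is attributable to exactly one label and ground truth stays unambiguous.
site_id: demo
labels:
  - {label_id: colitis, display_name: colitis, synset: [immune colitis]}
  - {label_id: pneumonitis, display_name: pneumonitis, synset: [lung inflammation]}
  - {label_id: rash, display_name: rash, synset: [dermatitis]}
  - {label_id: hepatitis, display_name: hepatitis, synset: [transaminitis]}
  - {label_id: hypothyroidism, display_name: hypothyroidism, synset: [underactive thyroid]}
ici_drugs: [atezolizumab, ipilimumab, nivolumab, pembrolizumab]
category_map:
  colitis: Gastrointestinal
  pneumonitis: Pulmonary
  rash: Dermatologic
  hepatitis: Gastrointestinal
  hypothyroidism: Endocrine
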