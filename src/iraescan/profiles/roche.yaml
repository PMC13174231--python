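# Example clinical-trial profile: one safety narrative per patient, labels
# abstracted from adverse-event preferred terms; all patients on a PD-L1 inhibitor.
site_id: Roche
labels:
  - {label_id: pneumonitis, display_name: pneumonitis, synset: [lung inflammation]}
  - {label_id: colitis, display_name: colitis, synset: [diarrhoea]}
  - {label_id: rash, display_name: rash, synset: [dermatitis]}
  - {label_id: hepatitis, display_name: hepatitis, synset: [transaminitis]}
  - {label_id: hypothyroidism, display_name: hypothyroidism, synset: [underactive thyroid]}
  - {label_id: pyrexia, display_name: pyrexia, synset: [fever]}
  - {label_id: bladder_tamponade, display_name: bladder tamponade, synset: []}
  - {label_id: ascending_flaccid_paralysis, display_name: ascending flaccid paralysis, synset: []}
  - {label_id: wheezing, display_name: wheezing, synset: []}
  - {label_id: influenza_like_illness, display_name: influenza-like illness, synset: [influenza-like symptoms, influenza]}
  - {label_id: ards, display_name: ARDS, synset: [acute respiratory distress syndrome]}
  - {label_id: pleuritis, display_name: pleuritis, synset: [pleurisy]}
  - {label_id: myocarditis, display_name: myocarditis, synset: []}
  - {label_id: thrombocytopenia, display_name: thrombocytopenia, synset: [low platelets]}
  - {label_id: nephritis, display_name: nephritis, synset: [kidney inflammation]}
ici_drugs: [atezolizumab]
category_map:
  pneumonitis: Pulmonary
  colitis: Gastrointestinal
  rash: Dermatologic
  hepatitis: Gastrointestinal
  hypothyroidism: Endocrine
  pyrexia: Other
  bladder_tamponade: Other
  ascending_flaccid_paralysis: Neurologic
  wheezing: Pulmonary
  influenza_like_illness: Pulmonary
  ards: Pulmonary
  pleuritis: Pulmonary
  myocarditis: Cardiovascular
  thrombocytopenia: Haematological
  nephritis: Renal
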