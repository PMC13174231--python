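# Example EHR-site profile: fine-grained labels, with colitis and diarrhoea
# annotated separately. Reconstructs only labels named in published summaries;
# synsets beyond the neuropathy example are package-chosen illustrations.
site_id: VUMC
labels:
  - {label_id: neuropathy, display_name: neuropathy, synset: [neurotox, neurotoxicity]}
  - {label_id: hypothyroid, display_name: hypothyroid, synset: [hypothyroidism, underactive thyroid]}
  - {label_id: myasthenia_gravis, display_name: myasthenia gravis, synset: [MG]}
  - {label_id: rash, display_name: rash, synset: [dermatitis, skin eruption]}
  - {label_id: colitis, display_name: colitis, synset: []}
  - {label_id: diarrhoea, display_name: diarrhoea, synset: [diarrhea]}
  - {label_id: adrenal_insufficiency, display_name: adrenal insufficiency, synset: [adrenal crisis]}
  - {label_id: hepatitis, display_name: hepatitis, synset: [liver inflammation, transaminitis, elevated LFTs]}
  - {label_id: arthralgia, display_name: arthralgia, synset: []}
  - {label_id: duodenitis, display_name: duodenitis, synset: []}
  - {label_id: pancreatitis, display_name: pancreatitis, synset: []}
  - {label_id: hypophysitis, display_name: hypophysitis, synset: [pituitary inflammation]}
  - {label_id: mucositis, display_name: mucositis, synset: []}
  - {label_id: arthritis, display_name: arthritis, synset: [inflammatory arthritis]}
  - {label_id: pneumonitis, display_name: pneumonitis, synset: [lung inflammation]}
  - {label_id: joint_pain, display_name: joint pain, synset: []}
  - {label_id: fever, display_name: fever, synset: [febrile episode]}
  - {label_id: myalgia, display_name: myalgia, synset: [muscle aches]}
  - {label_id: haemolytic_anaemia, display_name: haemolytic anaemia, synset: [hemolytic anemia]}
  - {label_id: bullous_pemphigoid, display_name: bullous pemphigoid, synset: []}
ici_drugs: [atezolizumab, avelumab, durvalumab, ipilimumab, nivolumab, pembrolizumab]
category_map:
  neuropathy: Neurologic
  hypothyroid: Endocrine
  myasthenia_gravis: Neurologic
  rash: Dermatologic
  colitis: Gastrointestinal
  diarrhoea: Gastrointestinal
  adrenal_insufficiency: Endocrine
  hepatitis: Gastrointestinal
  arthralgia: Musculoskeletal and Rheumatologic
  duodenitis: Gastrointestinal
  pancreatitis: Gastrointestinal
  hypophysitis: Endocrine
  mucositis: Gastrointestinal
  arthritis: Musculoskeletal and Rheumatologic
  pneumonitis: Pulmonary
  joint_pain: Musculoskeletal and Rheumatologic
  fever: Other
  myalgia: Musculoskeletal and Rheumatologic
  haemolytic_anaemia: Haematological
  bullous_pemphigoid: Dermatologic
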