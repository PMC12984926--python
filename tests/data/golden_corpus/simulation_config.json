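{
  "n_conditions": 30,
  "conditions_per_study": 3,
  "n_null_sites": 17,
  "n_pos_partners": 1,
  "n_neg_partners": 1,
  "anchor_detection_prob": 0.5,
  "null_detection_prob": 0.25,
  "agreement_prob": 0.9,
  "partner_detection_coupling": 0.9,
  "up_prob": 0.5,
  "fc_up_mu": 0.5877866649021191,
  "fc_up_sigma": 0.25,
  "fc_down_mu": -0.5978370007556204,
  "fc_down_sigma": 0.25,
  "near_miss_fraction": 0.1,
  "n_profiling_datasets": 10,
  "anchor_protein": "PKN1",
  "anchor_site": "S562",
  "seed": 42
}
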