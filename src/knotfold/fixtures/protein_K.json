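{
  "target": "K",
  "search_seed": 907,
  "spec": {
    "chain_length": 41,
    "n_contacts": 40,
    "knot_type": "trefoil",
    "core_range": [
      3,
      22
    ],
    "n_core_contacts": 8,
    "abs_contact_order": 17.2
  },
  "verification": {
    "violations": [],
    "n_contacts": 40,
    "sum_separations": 686,
    "knot_core_end_deletion": [
      3,
      22
    ],
    "knot_core_exhaustive": [
      3,
      22
    ],
    "alexander_det": 3,
    "head_contact_load_beads_2_3": 7,
    "terminus_burial": [
      0,
      0
    ]
  }
}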