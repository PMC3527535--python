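{
  "target": "U",
  "search_seed": 3,
  "construction": "independent constrained design (seed below), then a constraint-preserving anneal maximizing bead-site coincidence with protein_K; 90% coincidence was not attainable for this knotted realization - see the achieved value",
  "spec": {
    "chain_length": 40,
    "n_contacts": 40,
    "knot_type": "unknot",
    "abs_contact_order": 16.0,
    "overlap_with_K_percent_target": 90.0,
    "overlap_with_K_percent_achieved": 87.5
  },
  "verification": {
    "violations": [],
    "n_contacts": 40,
    "sum_separations": 640,
    "alexander_det": 1,
    "superposition_overlap_percent": 87.5
  }
}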