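{
  "type": "object",
  "required": [
    "fingerprint",
    "seed",
    "version",
    "counts",
    "functional_groups",
    "prey_pairwise",
    "clusters",
    "diets",
    "epsilon",
    "convergence",
    "warnings",
    "config"
  ],
  "properties": {
    "fingerprint": {"type": "string"},
    "seed": {"type": "integer"},
    "version": {"type": "string"},
    "counts": {
      "type": "object",
      "required": ["prey_rows_in", "consumer_rows_in", "consumers_per_period"]
    },
    "functional_groups": {"type": "object"},
    "prey_pairwise": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["group_a", "group_b", "pseudo_f", "p_value", "p_adjusted"],
        "properties": {
          "group_a": {"type": "string"},
          "group_b": {"type": "string"},
          "pseudo_f": {"type": "number"},
          "p_value": {"type": "number"},
          "p_adjusted": {"type": "number"}
        }
      }
    },
    "fa": {"type": ["object", "null"]},
    "clusters": {"type": "object"},
    "diets": {"type": "object"},
    "epsilon": {"type": "object"},
    "convergence": {"type": "object"},
    "warnings": {"type": "array"},
    "config": {"type": "object"}
  }
}
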