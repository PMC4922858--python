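{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "splicekin pipeline report",
  "type": "object",
  "required": ["manifest", "tally", "fits"],
  "properties": {
    "manifest": {
      "type": "object",
      "required": ["preset", "n_molecules", "seed", "frame_spacing_s",
                   "frame_duration_s", "t_max_s", "tolerance_s"],
      "properties": {
        "preset": {"type": "string"},
        "n_molecules": {"type": "integer"},
        "seed": {"type": "integer"},
        "frame_spacing_s": {"type": "number"},
        "frame_duration_s": {"type": "number"},
        "t_max_s": {"type": "number"},
        "tolerance_s": {"type": "number"}
      }
    },
    "tally": {
      "type": "object",
      "required": ["counts", "total", "percentages"],
      "properties": {
        "counts": {"type": "object"},
        "total": {"type": "integer"},
        "percentages": {"type": "object"}
      }
    },
    "n_unmatched": {"type": "object"},
    "multi_binding": {"type": "object"},
    "rebinding": {"type": ["object", "null"]},
    "ordering": {"type": ["object", "null"]},
    "fits": {"type": "object"}
  }
}
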