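{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "tscmr pipeline configuration",
  "description": "YAML configuration accepted by `tscmr pipeline --config`. Paths point at pre-clumped, delimited GWAS summary-statistic files.",
  "type": "object",
  "required": ["exposure_path", "outcome_path", "confounder_paths"],
  "additionalProperties": false,
  "properties": {
    "exposure_path": {"type": "string"},
    "outcome_path": {"type": "string"},
    "confounder_paths": {
      "type": "array",
      "items": {"type": "string"},
      "minItems": 1
    },
    "out_dir": {"type": ["string", "null"]},
    "instruments": {
      "type": ["array", "null"],
      "items": {"type": "string"},
      "description": "Explicit cis instrument snp_ids; omit to select at p_threshold."
    },
    "p_threshold": {"type": "number", "exclusiveMinimum": 0, "maximum": 1, "default": 5e-8},
    "confounder_p_threshold": {"type": "number", "exclusiveMinimum": 0, "maximum": 1, "default": 5e-8},
    "q_pvalue_threshold": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 1, "default": 0.05},
    "palindrome_eaf_window": {"type": "number", "minimum": 0, "exclusiveMaximum": 0.5, "default": 0.08},
    "n_boot": {"type": "integer", "minimum": 0, "default": 10000},
    "estimator_n_boot": {"type": "integer", "minimum": 100, "default": 1000},
    "seed": {"type": "integer", "default": 0},
    "first_order": {"type": "boolean", "default": false},
    "bandwidth_factor": {"type": "number", "exclusiveMinimum": 0, "default": 1.0},
    "exposure_column_map": {"type": ["object", "null"], "additionalProperties": {"type": "string"}},
    "outcome_column_map": {"type": ["object", "null"], "additionalProperties": {"type": "string"}},
    "confounder_column_maps": {
      "type": ["array", "null"],
      "items": {"type": ["object", "null"], "additionalProperties": {"type": "string"}}
    }
  }
}
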