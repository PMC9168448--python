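{
  "type": "object",
  "required": ["provenance", "config", "n_recordings", "n_unique_subjects",
               "n_vertices", "correlation_stimulus", "correlation_silence",
               "thalamic", "stim_vs_silence", "timing_s"],
  "properties": {
    "provenance": {
      "type": "object",
      "required": ["package", "version", "config_hash", "master_seed",
                   "stage_seeds", "timestamp"],
      "properties": {
        "package": {"type": "string"},
        "version": {"type": "string"},
        "config_hash": {"type": "string"},
        "master_seed": {"type": "integer"},
        "stage_seeds": {"type": "object"},
        "timestamp": {"type": "string"}
      }
    },
    "config": {"type": "object"},
    "n_recordings": {"type": "integer"},
    "n_unique_subjects": {"type": "integer"},
    "n_vertices": {"type": "integer"},
    "correlation_stimulus": {
      "type": "object",
      "required": ["n_clusters", "n_significant", "clusters", "max_abs_rho"],
      "properties": {
        "n_clusters": {"type": "integer"},
        "n_significant": {"type": "integer"},
        "max_abs_rho": {"type": "number"},
        "clusters": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["n_vertices", "mass", "p_mc", "significant"],
            "properties": {
              "n_vertices": {"type": "integer"},
              "mass": {"type": "number"},
              "p_mc": {"type": "number"},
              "significant": {"type": "boolean"}
            }
          }
        }
      }
    },
    "correlation_silence": {
      "type": "object",
      "required": ["n_clusters", "n_significant", "clusters", "max_abs_rho"]
    },
    "thalamic": {
      "type": "object",
      "required": ["n_nuclei", "n_significant", "min_p_maxstat"],
      "properties": {
        "n_nuclei": {"type": "integer"},
        "n_significant": {"type": "integer"},
        "min_p_maxstat": {"type": "number"}
      }
    },
    "stim_vs_silence": {
      "type": "object",
      "required": ["metric", "z", "p", "n"],
      "properties": {
        "metric": {"type": "string"},
        "z": {"type": "number"},
        "p": {"type": "number"},
        "n": {"type": "integer"}
      }
    },
    "timing_s": {"type": "object"}
  }
}
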