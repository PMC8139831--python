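{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "lineagecircuits pipeline report",
  "type": "object",
  "required": [
    "schema_version",
    "seed",
    "config",
    "n_neurons",
    "n_connectors",
    "morphometrics",
    "synapse_maps",
    "connectivity",
    "cohort_comparison",
    "null_model"
  ],
  "properties": {
    "schema_version": {"const": 1},
    "seed": {"type": "integer"},
    "config": {"type": "object"},
    "n_neurons": {"type": "integer", "minimum": 1},
    "n_connectors": {"type": "integer", "minimum": 0},
    "morphometrics": {
      "type": "object",
      "required": ["temporal_bins", "temporal_assignment_accuracy", "hemilineage_ari"],
      "properties": {
        "temporal_bins": {
          "type": "object",
          "required": ["t1", "t2", "t3"],
          "properties": {
            "t1": {"type": "number"},
            "t2": {"type": "number"},
            "t3": {"type": "number"}
          }
        },
        "temporal_assignment_accuracy": {"type": "number", "minimum": 0, "maximum": 1},
        "hemilineage_ari": {"type": "number"},
        "n_neurons": {"type": "integer"}
      }
    },
    "synapse_maps": {
      "type": "object",
      "required": ["sigma", "omega", "n_scored_pre", "n_scored_post"],
      "properties": {
        "sigma": {"type": "number"},
        "omega": {"type": "number"},
        "n_scored_pre": {"type": "integer"},
        "n_scored_post": {"type": "integer"},
        "density_maps": {
          "type": "object",
          "additionalProperties": {
            "type": "object",
            "required": ["contour_level", "enclosed_mass"],
            "properties": {
              "contour_level": {"type": "number"},
              "enclosed_mass": {"type": "number"}
            }
          }
        }
      }
    },
    "connectivity": {
      "type": "object",
      "required": ["n_edges", "binarize_threshold"],
      "properties": {
        "n_edges": {"type": "integer"},
        "binarize_threshold": {"type": "integer"},
        "n_premotor": {"type": "integer"},
        "n_postsensory": {"type": "integer"},
        "median_finite_network_distance": {"type": ["number", "null"]}
      }
    },
    "cohort_comparison": {
      "type": "object",
      "required": ["summary", "tests"],
      "properties": {
        "summary": {"type": "array", "items": {"type": "object"}},
        "tests": {"type": "array", "items": {"type": "object"}}
      }
    },
    "null_model": {
      "type": "object",
      "required": ["mode", "n_iter", "observed", "p", "variant"],
      "properties": {
        "mode": {"enum": ["overlap", "input_degree"]},
        "overlap_threshold": {"type": "number"},
        "n_iter": {"type": "integer"},
        "seed": {"type": ["integer", "null"]},
        "observed": {"type": "number"},
        "variant": {"enum": ["pair_both", "cohort_pair", "per_neuron"]},
        "p": {"type": "number", "exclusiveMinimum": 0, "maximum": 1}
      }
    }
  }
}
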