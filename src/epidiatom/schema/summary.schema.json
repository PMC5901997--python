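{
 "type": "object",
 "required": ["seed", "parameters", "channels", "mantel", "distance_comparison", "guilds"],
 "properties": {
  "seed": {"type": "integer"},
  "parameters": {
   "type": "object",
   "required": ["k", "nmds_dimensions", "nmds_restarts", "n_permutations", "otu_similarity"]
  },
  "channels": {
   "type": "object",
   "required": ["microscopy", "metabarcoding"],
   "properties": {
    "microscopy": {
     "type": "object",
     "required": ["mean_bray_curtis", "nmds_stress", "partition", "medoids"]
    },
    "metabarcoding": {
     "type": "object",
     "required": ["mean_bray_curtis", "nmds_stress", "partition", "medoids"]
    }
   }
  },
  "mantel": {
   "type": "object",
   "required": ["r", "r_squared", "p", "n_permutations"],
   "properties": {
    "r": {"type": "number"},
    "r_squared": {"type": "number"},
    "p": {"type": "number"}
   }
  },
  "distance_comparison": {
   "type": "object",
   "required": ["mean_metabarcoding", "mean_microscopy", "t_statistic", "p_parametric", "p_permutation"]
  },
  "cryptic": {
   "type": "object",
   "required": ["threshold", "n_groups", "groups", "fit"]
  },
  "guilds": {"type": "object"}
 }
}
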