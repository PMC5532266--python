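{
  "description": "Youden-optimal perfusion cutoffs and voxel-wise AUC values from the same 161-patient multicenter cohort, per perfusion parameter and recanalization group. Units: CBF ml/100g/min, CBV ml/100g, MTT and TTD seconds.",
  "models": [
    {"parameter": "CBF", "group": "RECANALIZED", "cutoff": 33.0, "direction": "LOWER_IS_POSITIVE", "auc": 0.671},
    {"parameter": "CBV", "group": "RECANALIZED", "cutoff": 2.4, "direction": "LOWER_IS_POSITIVE", "auc": 0.628},
    {"parameter": "MTT", "group": "RECANALIZED", "cutoff": 10.0, "direction": "HIGHER_IS_POSITIVE", "auc": 0.535},
    {"parameter": "TTD", "group": "RECANALIZED", "cutoff": 9.7, "direction": "HIGHER_IS_POSITIVE", "auc": 0.614},
    {"parameter": "CBF", "group": "PERSISTENT", "cutoff": 34.0, "direction": "LOWER_IS_POSITIVE", "auc": 0.673},
    {"parameter": "CBV", "group": "PERSISTENT", "cutoff": 2.4, "direction": "LOWER_IS_POSITIVE", "auc": 0.593},
    {"parameter": "MTT", "group": "PERSISTENT", "cutoff": 9.0, "direction": "HIGHER_IS_POSITIVE", "auc": 0.586},
    {"parameter": "TTD", "group": "PERSISTENT", "cutoff": 8.2, "direction": "HIGHER_IS_POSITIVE", "auc": 0.673}
  ]
}
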