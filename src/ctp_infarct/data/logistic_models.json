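{
  "description": "Univariate voxel-wise logistic infarct models (intercept, coefficient per predictor unit) estimated in a 161-patient multicenter endovascular stroke cohort, per perfusion parameter and recanalization group.",
  "models": [
    {"parameter": "CBF", "group": "RECANALIZED", "intercept": -1.172, "coefficient": -0.0211},
    {"parameter": "CBV", "group": "RECANALIZED", "intercept": -1.323, "coefficient": -0.2097},
    {"parameter": "MTT", "group": "RECANALIZED", "intercept": -2.281, "coefficient": 0.0477},
    {"parameter": "TTD", "group": "RECANALIZED", "intercept": -2.627, "coefficient": 0.0714},
    {"parameter": "CBF", "group": "PERSISTENT", "intercept": 0.1188, "coefficient": -0.0199},
    {"parameter": "CBV", "group": "PERSISTENT", "intercept": -0.2044, "coefficient": -0.1371},
    {"parameter": "MTT", "group": "PERSISTENT", "intercept": -1.137, "coefficient": 0.0733},
    {"parameter": "TTD", "group": "PERSISTENT", "intercept": -1.573, "coefficient": 0.0987}
  ]
}
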