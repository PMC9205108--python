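{
  "notes": "Published Canadian FACT-8D conditional-logit estimates. Each dimension-level coefficient is the interaction of that level's dummy with duration; level 1 is the reference (0). 'beta' lists levels 1..5. Model 1 = unweighted unconstrained; Model 2 = raked, unconstrained; Model 3 = raked with non-monotone levels collapsed. Model 3 'spec' records the collapsing pattern: 'reference' groups are fixed at 0, 'groups' are estimated (merged levels share one coefficient).",
  "model1": {
    "alpha": 0.331,
    "alpha_se": 0.013,
    "beta": {
      "pain":    [0.0,  0.003, -0.020, -0.060, -0.136],
      "fatigue": [0.0, -0.002, -0.021, -0.040, -0.050],
      "nausea":  [0.0, -0.032, -0.044, -0.061, -0.089],
      "sleep":   [0.0,  0.020,  0.015, -0.040, -0.006],
      "work":    [0.0, -0.009, -0.014, -0.034, -0.076],
      "support": [0.0, -0.023, -0.001, -0.045, -0.067],
      "sadness": [0.0, -0.009, -0.035, -0.038, -0.058],
      "worry":   [0.0, -0.031, -0.019, -0.039, -0.049]
    },
    "log_likelihood": -15009.31,
    "n_parameters": 33,
    "aic": 30084.62,
    "bic": 30375.13
  },
  "model2": {
    "alpha": 0.345,
    "alpha_se": 0.026,
    "beta": {
      "pain":    [0.0,  0.014, -0.025, -0.062, -0.148],
      "fatigue": [0.0, -0.030, -0.038, -0.048, -0.069],
      "nausea":  [0.0, -0.036, -0.047, -0.063, -0.103],
      "sleep":   [0.0,  0.024,  0.036, -0.019,  0.010],
      "work":    [0.0, -0.026, -0.040, -0.039, -0.088],
      "support": [0.0, -0.034,  0.009, -0.038, -0.064],
      "sadness": [0.0,  0.001, -0.050, -0.035, -0.069],
      "worry":   [0.0, -0.046, -0.021, -0.050, -0.033]
    },
    "log_likelihood": -14602.54,
    "n_parameters": 33,
    "aic": 29271.07,
    "bic": 29560.89
  },
  "model3": {
    "alpha": 0.366,
    "alpha_se": 0.023,
    "beta": {
      "pain":    [0.0,  0.0,   -0.021, -0.072, -0.149],
      "fatigue": [0.0, -0.020, -0.028, -0.053, -0.060],
      "nausea":  [0.0, -0.036, -0.055, -0.059, -0.109],
      "sleep":   [0.0,  0.0,    0.0,   -0.028, -0.028],
      "work":    [0.0, -0.021, -0.033, -0.033, -0.085],
      "support": [0.0, -0.008, -0.008, -0.044, -0.072],
      "sadness": [0.0,  0.0,   -0.047, -0.047, -0.068],
      "worry":   [0.0, -0.035, -0.035, -0.043, -0.043]
    },
    "spec": {
      "pain":    {"reference": [[2]],      "groups": [[3], [4], [5]]},
      "fatigue": {"reference": [],         "groups": [[2], [3], [4], [5]]},
      "nausea":  {"reference": [],         "groups": [[2], [3], [4], [5]]},
      "sleep":   {"reference": [[2, 3]],   "groups": [[4, 5]]},
      "work":    {"reference": [],         "groups": [[2], [3, 4], [5]]},
      "support": {"reference": [],         "groups": [[2, 3], [4], [5]]},
      "sadness": {"reference": [[2]],      "groups": [[3, 4], [5]]},
      "worry":   {"reference": [],         "groups": [[2, 3], [4, 5]]}
    },
    "log_likelihood": -14655.46,
    "n_parameters": 23,
    "aic": 29540.03,
    "bic": 29724.46
  }
}
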