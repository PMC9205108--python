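{
  "label": "FACT-8D Canada 2023",
  "country": "Canada",
  "source_model": "raked conditional logit with monotonicity imposed by level collapsing",
  "notes": "Published decrements stored verbatim (3 dp, magnitudes). The published pain row (0.077/0.187/0.384) differs from -beta/alpha of the published constrained-model pain coefficients (0.057/0.197/0.407); the published table is authoritative for scoring and is kept as printed.",
  "dimensions": {
    "pain":    [0.0, 0.0,   0.077, 0.187, 0.384],
    "fatigue": [0.0, 0.054, 0.075, 0.144, 0.164],
    "nausea":  [0.0, 0.099, 0.149, 0.162, 0.298],
    "sleep":   [0.0, 0.0,   0.0,   0.077, 0.077],
    "work":    [0.0, 0.057, 0.090, 0.090, 0.231],
    "support": [0.0, 0.022, 0.022, 0.120, 0.195],
    "sadness": [0.0, 0.0,   0.127, 0.127, 0.185],
    "worry":   [0.0, 0.097, 0.097, 0.097, 0.118]
  }
}
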