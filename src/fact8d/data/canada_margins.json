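{
  "notes": "Canadian census margin targets and study-sample proportions for the valuation survey's demographic variables. 'population' values are as published (2 dp; region and education rows do not sum exactly to 1 because of printed rounding — the loader renormalizes). 'sample' holds the achieved study-sample proportions used as default sampling distributions for the skewed (non-quota) variables. Quota variables (sex, age, region) were sampled to census targets; language, education and self-rated health were not and are the raking candidates.",
  "quota_variables": ["sex", "age", "region"],
  "skewed_variables": ["language", "education", "health"],
  "variables": {
    "sex": {
      "population": {"male": 0.48, "female": 0.52},
      "sample": {"male": 0.48, "female": 0.52}
    },
    "age": {
      "population": {"18-29": 0.20, "30-39": 0.17, "40-49": 0.21, "50-59": 0.18, "60-69": 0.11, "70+": 0.13},
      "sample": {"18-29": 0.19, "30-39": 0.17, "40-49": 0.21, "50-59": 0.18, "60-69": 0.11, "70+": 0.13}
    },
    "region": {
      "population": {"AB": 0.12, "BC": 0.13, "MB": 0.04, "NB": 0.02, "NL": 0.02, "NS": 0.03, "NT": 0.001, "NU": 0.001, "ON": 0.39, "QC": 0.23, "PE": 0.004, "SK": 0.04, "YT": 0.001},
      "sample": {"AB": 0.11, "BC": 0.13, "MB": 0.04, "NB": 0.02, "NL": 0.01, "NS": 0.03, "NT": 0.001, "NU": 0.0, "ON": 0.39, "QC": 0.23, "PE": 0.004, "SK": 0.04, "YT": 0.001}
    },
    "language": {
      "population": {"english": 0.58, "french": 0.22, "other": 0.20},
      "sample": {"english": 0.78, "french": 0.19, "other": 0.03}
    },
    "education": {
      "population": {"none": 0.15, "high_school": 0.24, "trades": 0.12, "college": 0.20, "below_bachelor": 0.05, "bachelor_plus": 0.23},
      "sample": {"none": 0.03, "high_school": 0.20, "trades": 0.07, "college": 0.25, "below_bachelor": 0.13, "bachelor_plus": 0.33}
    },
    "health": {
      "population": {"excellent": 0.22, "very_good": 0.36, "good": 0.29, "fair": 0.11, "poor": 0.02},
      "sample": {"excellent": 0.12, "very_good": 0.39, "good": 0.33, "fair": 0.13, "poor": 0.03}
    }
  }
}
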