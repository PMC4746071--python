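{
  "thresholds": [-10.566, -6.682, -3.33],
  "coefficients": {
    "hii": -0.249,
    "mhi": -1.915,
    "age": -0.048,
    "sex": -0.036
  },
  "covariate_spec": [
    {"name": "hii", "kind": "continuous", "description": "Health Impact Index score (non-negative integer)"},
    {"name": "mhi", "kind": "continuous", "description": "mean mental-distress score on the 1-4 scale"},
    {"name": "age", "kind": "continuous", "description": "age in years"},
    {"name": "sex", "kind": "binary", "reference": "female", "description": "0=female, 1=male"}
  ],
  "convention_note": "Cumulative probabilities follow P(Y<=i | x) = logistic(Z_i - x.beta) for the ordered outcome Y (1=poor ... 4=very good self-reported health). Negative coefficients are harmful: they raise the probability of reporting lower SRH. The odds ratio of reporting lower SRH per unit of a covariate is exp(-beta)."
}
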