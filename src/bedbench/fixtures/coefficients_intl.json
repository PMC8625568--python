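{
  "description": "Published regression coefficients from the predecessor international model (166 nations, 2015 data), kept as a documented reference only; the outcome there is the untransformed bed rate. Not used by the pipeline.",
  "outcome": "beds per 100,000 (untransformed)",
  "terms": ["const", "disability", "disability_sq", "cmh", "cmh_sq", "cmh_cu", "married", "life_expectancy"],
  "coefficients": {
    "const":           {"b": 356.205,    "beta": null,   "t": 6.718,  "partial_r": null},
    "disability":      {"b": -23028.38,  "beta": -3.338, "t": -5.631, "partial_r": -0.388},
    "disability_sq":   {"b": 424811.3,   "beta": 3.36,   "t": 5.809,  "partial_r": 0.399},
    "cmh":             {"b": 31.687,     "beta": 0.667,  "t": 3.623,  "partial_r": 0.262},
    "cmh_sq":          {"b": -12.402,    "beta": -1.616, "t": -3.281, "partial_r": -0.239},
    "cmh_cu":          {"b": 1.114,      "beta": 1.192,  "t": 3.139,  "partial_r": 0.229},
    "married":         {"b": -1.403,     "beta": -0.308, "t": -4.652, "partial_r": -0.329},
    "life_expectancy": {"b": 73.519,     "beta": 0.321,  "t": 3.989,  "partial_r": 0.0286}
  },
  "equation_statistics": {
    "r": 0.667,
    "r_squared": 0.444,
    "adj_r_squared": 0.423,
    "df_regression_printed": 178,
    "df_residual_printed": 7,
    "f": 20.389,
    "p": 0.0,
    "mean_cooks_distance": 0.009,
    "mean_standardized_residual": 0.0
  }
}
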