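{
  "description": "Published regression coefficients for the 2018 U.S. state model of psychiatric inpatient bed rates. Outcome is the reciprocal bed rate (1/beds-per-100,000); negative coefficients therefore correspond to positive associations with the bed rate itself. Fit was weighted by relative state population.",
  "outcome": "reciprocal bed rate (1 / beds per 100,000)",
  "terms": ["const", "disability", "disability_sq", "cmh", "cmh_sq", "cmh_cu", "married", "life_expectancy"],
  "coefficients": {
    "const":           {"b": 0.073,  "beta": null,   "t": 0.549,  "partial_r": null},
    "disability":      {"b": 1.905,  "beta": 1.456,  "t": 1.013,  "partial_r": 0.153},
    "disability_sq":   {"b": -20.26, "beta": -1.676, "t": -1.165, "partial_r": -0.175},
    "cmh":             {"b": 0.001,  "beta": 0.038,  "t": 0.156,  "partial_r": 0.024},
    "cmh_sq":          {"b": 0.005,  "beta": 0.273,  "t": 1.598,  "partial_r": 0.237},
    "cmh_cu":          {"b": -0.004, "beta": -0.403, "t": -1.580, "partial_r": -0.235},
    "married":         {"b": 0.002,  "beta": 0.349,  "t": 2.642,  "partial_r": 0.375},
    "life_expectancy": {"b": -0.002, "beta": -0.349, "t": -1.655, "partial_r": -0.245}
  },
  "equation_statistics": {
    "r": 0.57,
    "r_squared": 0.325,
    "adj_r_squared": 0.214,
    "df_regression_printed": 43,
    "df_residual_printed": 7,
    "f": 2.936,
    "p": 0.013,
    "mean_cooks_distance": 0.007,
    "mean_standardized_residual": 0.0
  },
  "scenario_cmh_index": 1.0206,
  "notes": "The printed regression/residual degrees of freedom (43/7) appear transposed: the model has 7 non-intercept terms and 50 - 8 = 42 residual df. The published narrative also cites F = 2.9935 where the table prints 2.936; both are recorded here and neither is recomputed."
}
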