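{
  "comment": "Published stepwise-regression models of the portable pediatric body-composition analyzer validation study (N = 200). 'table' holds the canonical coefficient table with full diagnostics; 'equation_text' holds the variants printed in the study's equation listing where they differ (BF model: BMI coefficient sign; FFM model: BF coefficient value). Stored verbatim, including the reported MultipleR/R-Square pairs that are mutually inconsistent; those are metadata, never validated against each other.",
  "models": {
    "BMI": {
      "table": {
        "intercept": -0.833,
        "coefficients": {"BF": 0.417, "FFM": 0.358, "TBW": -0.090, "MM": -0.139, "BM": 7.654},
        "standard_errors": {"intercept": 2.894, "BF": 0.086, "FFM": 0.196, "TBW": 0.201, "MM": 0.124, "BM": 2.986},
        "t_stats": {"intercept": -0.288, "BF": 4.834, "FFM": 1.827, "TBW": -0.446, "MM": -1.120, "BM": 2.563},
        "p_values": {"intercept": 0.774, "BF": 0.000, "FFM": 0.071, "TBW": 0.657, "MM": 0.266, "BM": 0.012},
        "multiple_r": 0.842, "r_squared": 0.909, "f_stat": 45.71, "sig_f": 0.002
      },
      "equation_text": {
        "intercept": -0.833,
        "coefficients": {"BF": 0.417, "FFM": 0.358, "TBW": -0.090, "MM": -0.139, "BM": 7.654}
      }
    },
    "BF": {
      "table": {
        "intercept": -3.081,
        "coefficients": {"FFM": 0.560, "TBW": 0.450, "MM": -0.116, "BM": -0.390, "BMI": 0.477},
        "standard_errors": {"intercept": 3.082, "FFM": 0.206, "TBW": 0.210, "MM": 0.133, "BM": 3.305, "BMI": 0.099},
        "t_stats": {"intercept": -1.000, "FFM": 2.720, "TBW": 2.140, "MM": -0.872, "BM": -0.118, "BMI": 4.834},
        "p_values": {"intercept": 0.320, "FFM": 0.008, "TBW": 0.035, "MM": 0.386, "BM": 0.906, "BMI": 0.000},
        "multiple_r": 0.869, "r_squared": 0.895, "f_stat": 58.07, "sig_f": 0.001
      },
      "equation_text": {
        "intercept": -3.081,
        "coefficients": {"FFM": 0.560, "TBW": 0.450, "MM": -0.116, "BM": -0.390, "BMI": -0.477}
      }
    },
    "FFM": {
      "table": {
        "intercept": 1.166,
        "coefficients": {"TBW": 0.144, "MM": 0.413, "BM": 3.586, "BMI": 0.096, "BF": 0.130},
        "standard_errors": {"intercept": 1.491, "TBW": 0.103, "MM": 0.048, "BM": 1.552, "BMI": 0.052, "BF": 0.048},
        "t_stats": {"intercept": 0.782, "TBW": 1.404, "MM": 8.562, "BM": 2.310, "BMI": 1.827, "BF": 2.720},
        "p_values": {"intercept": 0.436, "TBW": 0.164, "MM": 0.000, "BM": 0.023, "BMI": 0.071, "BF": 0.008},
        "multiple_r": 0.942, "r_squared": 0.888, "f_stat": 149.35, "sig_f": 0.002
      },
      "equation_text": {
        "intercept": 1.166,
        "coefficients": {"TBW": 0.144, "MM": 0.413, "BM": 3.586, "BMI": 0.096, "BF": 0.310}
      }
    },
    "TBW": {
      "table": {
        "intercept": 12.052,
        "coefficients": {"MM": 0.131, "BM": 6.467, "BMI": -0.024, "BF": 0.103, "FFM": 0.142},
        "standard_errors": {"intercept": 0.813, "MM": 0.062, "BM": 1.437, "BMI": 0.053, "BF": 0.048, "FFM": 0.101},
        "t_stats": {"intercept": 14.819, "MM": 2.104, "BM": 4.499, "BMI": -0.446, "BF": 2.140, "FFM": 1.404},
        "p_values": {"intercept": 0.000, "MM": 0.038, "BM": 0.000, "BMI": 0.657, "BF": 0.035, "FFM": 0.164},
        "multiple_r": 0.889, "r_squared": 0.891, "f_stat": 70.97, "sig_f": 0.001
      },
      "equation_text": {
        "intercept": 12.052,
        "coefficients": {"MM": 0.131, "BM": 6.467, "BMI": -0.024, "BF": 0.103, "FFM": 0.142}
      }
    },
    "MM": {
      "table": {
        "intercept": -9.155,
        "coefficients": {"BM": -1.502, "BMI": -0.095, "BF": -0.069, "FFM": 1.061, "TBW": 0.342},
        "standard_errors": {"intercept": 2.204, "BM": 2.554, "BMI": 0.085, "BF": 0.080, "FFM": 0.124, "TBW": 0.163},
        "t_stats": {"intercept": -4.153, "BM": -0.588, "BMI": -1.120, "BF": -0.872, "FFM": 8.562, "TBW": 2.104},
        "p_values": {"intercept": 0.000, "BM": 0.558, "BMI": 0.266, "BF": 0.386, "FFM": 0.000, "TBW": 0.038},
        "multiple_r": 0.893, "r_squared": 0.897, "f_stat": 73.75, "sig_f": 0.003
      },
      "equation_text": {
        "intercept": -9.155,
        "coefficients": {"BM": -1.502, "BMI": -0.095, "BF": -0.069, "FFM": 1.061, "TBW": 0.342}
      }
    },
    "BM": {
      "table": {
        "intercept": -0.194,
        "coefficients": {"BMI": 0.009, "BF": 0.000, "FFM": 0.015, "TBW": 0.027, "MM": -0.002},
        "standard_errors": {"intercept": 0.095, "BMI": 0.003, "BF": 0.003, "FFM": 0.006, "TBW": 0.006, "MM": 0.004},
        "t_stats": {"intercept": -2.053, "BMI": 2.563, "BF": -0.118, "FFM": 2.310, "TBW": 4.499, "MM": -0.588},
        "p_values": {"intercept": 0.043, "BMI": 0.012, "BF": 0.906, "FFM": 0.023, "TBW": 0.000, "MM": 0.558},
        "multiple_r": 0.874, "r_squared": 0.864, "f_stat": 60.916, "sig_f": 0.001
      },
      "equation_text": {
        "intercept": -0.194,
        "coefficients": {"BMI": 0.009, "BF": 0.000, "FFM": 0.015, "TBW": 0.027, "MM": -0.002}
      }
    }
  }
}
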