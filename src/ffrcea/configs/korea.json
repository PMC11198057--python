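{
  "name": "korea",
  "discount_rate_annual": 0.045,
  "wtp_per_qaly": 30000,
  "horizon_years": 10,
  "cycle_length_years": 1,
  "ffr_arm_mode": "hr_scaled_probability",
  "transitions": {
    "angio": {"p_mi_annual": 0.016, "p_death_annual": 0.056, "p_revasc_annual": 0.124},
    "ffr_observed": {"p_mi_annual": 0.013, "p_death_annual": 0.039, "p_revasc_annual": 0.128},
    "hr_death": {"point": 0.80, "ci_low": 0.70, "ci_high": 0.91},
    "hr_mi": {"point": 0.75, "ci_low": 0.59, "ci_high": 0.96},
    "hr_revasc": {"point": 1.00, "ci_low": 0.92, "ci_high": 1.08},
    "p_death_post_mi": 0.131
  },
  "costs": {
    "ffr_addon": 194,
    "annual_angina": 1483,
    "annual_mi": 1524,
    "revasc_no_mi": 1473,
    "revasc_with_mi": 1483,
    "death_related": 6441
  },
  "utilities": {
    "u_angina": 0.79,
    "u_mi": 0.67,
    "disutilities": {
      "atrial_fibrillation_with_angina": 0.084,
      "atrial_fibrillation_with_mi": 0.145,
      "congestive_heart_failure": 0.064,
      "diabetes_with_angina": 0.040,
      "diabetes_with_mi": 0.050
    }
  }
}
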