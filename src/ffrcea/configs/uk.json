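{
  "name": "uk",
  "discount_rate_annual": 0.035,
  "wtp_per_qaly": 40000,
  "horizon_years": 10,
  "cycle_length_years": 1,
  "ffr_arm_mode": "hr_scaled_probability",
  "transitions": {
    "angio": {"p_mi_annual": 0.087, "p_death_annual": 0.028, "p_revasc_annual": 0.095},
    "ffr_observed": {"p_mi_annual": 0.057, "p_death_annual": 0.017, "p_revasc_annual": 0.065},
    "hr_death": {"point": 0.58, "ci_low": 0.26, "ci_high": 1.32},
    "hr_mi": {"point": 0.66, "ci_low": 0.42, "ci_high": 1.04},
    "hr_revasc": {"point": 0.68, "ci_low": 0.45, "ci_high": 1.05},
    "p_death_post_mi": 0.016
  },
  "costs": {
    "ffr_addon": 375,
    "annual_angina": 406,
    "annual_mi": 1964,
    "revasc_no_mi": 2652,
    "revasc_with_mi": 3452,
    "death_related": 1629
  },
  "utilities": {
    "u_angina": 0.718,
    "u_mi": 0.683,
    "disutilities": {}
  }
}
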