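{
  "name": "us",
  "discount_rate_annual": 0.035,
  "wtp_per_qaly": 60000,
  "horizon_years": 10,
  "cycle_length_years": 1,
  "ffr_arm_mode": "hr_scaled_probability",
  "transitions": {
    "angio": {"p_mi_annual": 0.0079, "p_death_annual": 0.059, "p_revasc_annual": 0.034},
    "ffr_observed": {"p_mi_annual": 0.0064, "p_death_annual": 0.028, "p_revasc_annual": 0.038},
    "hr_death": {"point": 0.57, "ci_low": 0.45, "ci_high": 0.71},
    "hr_mi": {"point": 0.77, "ci_low": 0.47, "ci_high": 1.27},
    "hr_revasc": {"point": 1.04, "ci_low": 0.84, "ci_high": 1.28},
    "p_death_post_mi": 0.05
  },
  "costs": {
    "ffr_addon": 975,
    "annual_angina": 5225,
    "annual_mi": 27796,
    "revasc_no_mi": 26796,
    "revasc_with_mi": 36090,
    "death_related": 35818
  },
  "utilities": {
    "u_angina": 0.92,
    "u_mi": 0.85,
    "disutilities": {}
  }
}
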