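{
  "coefficients": {
    "ckdepi2009": {
      "age_base": 0.993,
      "alpha": {
        "female": -0.329,
        "male": -0.411
      },
      "black": 1.159,
      "female": 1.018,
      "kappa": {
        "female": 0.7,
        "male": 0.9
      },
      "scale": 141.0,
      "scr_exp": -1.209
    },
    "ckdepi2021": {
      "age_base": 0.9938,
      "alpha": {
        "female": -0.241,
        "male": -0.302
      },
      "female": 1.012,
      "kappa": {
        "female": 0.7,
        "male": 0.9
      },
      "scale": 142.0,
      "scr_exp": -1.2
    },
    "kfre4v": {
      "baseline_survival_5yr": {
        "non_north_american": 0.9365,
        "north_american": 0.8996
      },
      "beta": {
        "age_per_10yr": -0.2201,
        "egfr_per_5": -0.5567,
        "log_acr_mg_g": 0.451,
        "male": 0.2467
      },
      "center": {
        "age_per_10yr": 7.036,
        "egfr_per_5": 7.222,
        "log_acr_mg_g": 5.137,
        "male": 0.5642
      }
    },
    "mdrd": {
      "age_exp": -0.203,
      "black": 1.212,
      "female": 0.742,
      "scale": 175.0,
      "scr_exp": -1.154
    }
  },
  "notes": "Creatinine eGFR equations (MDRD IDMS, CKD-EPI 2009, CKD-EPI 2021 race-free) and the 4-variable 5-year Kidney Failure Risk Equation with North-American and non-North-American (recalibrated) baseline survivals.",
  "sha256": "492e574f9c2fed40edf859900b288096ce302a347a8bda7a220c94861f2abb65",
  "version": "2021.1"
}
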