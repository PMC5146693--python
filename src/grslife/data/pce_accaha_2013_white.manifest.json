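{
  "name": "pce_accaha_2013_white",
  "version": "1.0",
  "source": "Goff et al. (2013) ACC/AHA pooled cohort equations, white strata",
  "description": "10-year ASCVD risk; risk = 1 - S0^exp(LP - LPbar). Cohorts without a race variable are mapped to the white stratum.",
  "covariate_units": {
    "entry_age": "years",
    "sbp": "mmHg",
    "total_chol": "mmol/L (scaled to mg/dL by 38.67 inside the terms)",
    "hdl_chol": "mmol/L (scaled to mg/dL by 38.67 inside the terms)",
    "smoking": "0/1",
    "diabetes": "0/1",
    "bp_treatment": "0/1"
  },
  "strata": {
    "female": {"s0": 0.9665, "lp_mean": -29.18},
    "male": {"s0": 0.9144, "lp_mean": 61.18}
  }
}
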