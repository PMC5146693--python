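{
  "name": "frs_general_cvd_2008",
  "version": "1.0",
  "source": "D'Agostino et al. (2008), general cardiovascular disease sex-specific Cox functions",
  "description": "Framingham-style 10-year general CVD risk; risk = 1 - S0^exp(LP - LPbar).",
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
    "female": {"s0": 0.95012, "lp_mean": 26.1931},
    "male": {"s0": 0.88936, "lp_mean": 23.9802}
  }
}
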