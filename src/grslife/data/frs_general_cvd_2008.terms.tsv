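stratum	term	covariates	transforms	scales	coefficient
female	ln_age	entry_age	log	1	2.32888
female	ln_total_chol	total_chol	log	38.67	1.20904
female	ln_hdl_chol	hdl_chol	log	38.67	-0.70833
female	ln_sbp_untreated	sbp|bp_treatment	log|complement	1|1	2.76157
female	ln_sbp_treated	sbp|bp_treatment	log|identity	1|1	2.82263
female	smoking	smoking	identity	1	0.52873
female	diabetes	diabetes	identity	1	0.69154
male	ln_age	entry_age	log	1	3.06117
male	ln_total_chol	total_chol	log	38.67	1.12370
male	ln_hdl_chol	hdl_chol	log	38.67	-0.93263
male	ln_sbp_untreated	sbp|bp_treatment	log|complement	1|1	1.93303
male	ln_sbp_treated	sbp|bp_treatment	log|identity	1|1	1.99881
male	smoking	smoking	identity	1	0.65451
male	diabetes	diabetes	identity	1	0.57367
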