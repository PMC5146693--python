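stratum	term	covariates	transforms	scales	coefficient
female	ln_age	entry_age	log	1	-29.799
female	ln_age_sq	entry_age|entry_age	log|log	1|1	4.884
female	ln_total_chol	total_chol	log	38.67	13.540
female	ln_age_x_ln_total_chol	entry_age|total_chol	log|log	1|38.67	-3.114
female	ln_hdl_chol	hdl_chol	log	38.67	-13.578
female	ln_age_x_ln_hdl_chol	entry_age|hdl_chol	log|log	1|38.67	3.149
female	ln_sbp_treated	sbp|bp_treatment	log|identity	1|1	2.019
female	ln_sbp_untreated	sbp|bp_treatment	log|complement	1|1	1.957
female	smoking	smoking	identity	1	7.574
female	ln_age_x_smoking	entry_age|smoking	log|identity	1|1	-1.665
female	diabetes	diabetes	identity	1	0.661
male	ln_age	entry_age	log	1	12.344
male	ln_total_chol	total_chol	log	38.67	11.853
male	ln_age_x_ln_total_chol	entry_age|total_chol	log|log	1|38.67	-2.664
male	ln_hdl_chol	hdl_chol	log	38.67	-7.990
male	ln_age_x_ln_hdl_chol	entry_age|hdl_chol	log|log	1|38.67	1.769
male	ln_sbp_treated	sbp|bp_treatment	log|identity	1|1	1.797
male	ln_sbp_untreated	sbp|bp_treatment	log|complement	1|1	1.764
male	smoking	smoking	identity	1	7.837
male	ln_age_x_smoking	entry_age|smoking	log|identity	1|1	-1.795
male	diabetes	diabetes	identity	1	0.658
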