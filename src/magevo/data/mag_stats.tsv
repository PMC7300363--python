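mag_id	bin_size_kbp	completeness_checkm_pct	completeness_rinke_pct	contamination_pct
HMT_ATL	837.8	98.1	89.4	1.5
HMT_PAC	812.1	96.1	88.5	0.97
HMT_AAIW	697.5	78.1	72.6	0.97
HMT_NADW	670.8	76.6	75.2	0
HMT_AABW	814.8	88.8	77.0	0.97
ASW8	996.5	97.1	92.0	2.91
UBA57	613.3	62.7	66.4	0
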