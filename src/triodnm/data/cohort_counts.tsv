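cohort	n_trios	missense	synonymous	nonsense	canonical_splice	consensus_splice	frameshift_insertion	frameshift_deletion	inframe_insertion	inframe_deletion	callable_bases	ccds_snvs
id_study	41	48	11	5	2	1	4	8	1	1	2477702175	64
trio_controls	54	26	12	0	1	0	0	1	0	0	0	
asd_siblings	593	305	117	16	3	0	0	0	0	0	0	
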