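ancestry	locus	causal_variant	true_or	true_raf	true_par
EUR	APOE	APOE:snp1	2.6	0.15	0.193548
EUR	PICALM	PICALM:snp0	1.18	0.36	0.0608565
EUR	GBA1	GBA1:snp0	1.1	0.02	0.00199601
AFR	APOE	APOE:snp1	2.2	0.21	0.201278
AFR	PICALM	PICALM:snp0	1.18	0.3	0.0512334
AFR	GBA1	GBA1:snp0	1.55	0.07	0.0370727
EAS	APOE	APOE:snp1	2.9	0.1	0.159664
EAS	PICALM	PICALM:snp0	1.18	0.44	0.0733877
EAS	GBA1	GBA1:snp0	1.08	0.03	0.00239425
AMR	APOE	APOE:snp1	1.9	0.12	0.0974729
AMR	PICALM	PICALM:snp0	1.18	0.33	0.0560695
AMR	GBA1	GBA1:snp0	1	0.04	0
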