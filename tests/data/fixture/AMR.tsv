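variant_id	chrom	pos	effect_allele	other_allele	beta	se	p_value	eaf	locus	ancestry
APOE:snp0	1	1000000	A	G	0.459797	0.0441581	2.17405e-25	0.878364	APOE	AMR
APOE:snp1	1	1001000	A	G	0.658976	0.0394206	9.93369e-63	0.12	APOE	AMR
APOE:snp2	1	1002000	A	G	0.317753	0.0298109	1.58405e-26	0.624792	APOE	AMR
APOE:snp3	1	1003000	G	A	-0.30748	0.0497733	6.50756e-10	0.0926847	APOE	AMR
PICALM:snp0	2	1000000	A	G	0.178175	0.0302428	3.82714e-09	0.33	PICALM	AMR
PICALM:snp1	2	1001000	A	G	0.123072	0.0420404	0.0034174	0.863489	PICALM	AMR
PICALM:snp2	2	1002000	A	G	0.0251933	0.0471286	0.59295	0.895225	PICALM	AMR
GBA1:snp0	3	1000000	A	G	-0.013853	0.076024	0.855411	0.03755	GBA1	AMR
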