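variant_id	chrom	pos	effect_allele	other_allele	beta	se	p_value	eaf	locus	ancestry
APOE:snp0	1	1000000	A	G	0.51025	0.0234756	9.50554e-105	0.285842	APOE	EAS
APOE:snp1	1	1001000	A	G	1.03818	0.0299109	5.72845e-264	0.1	APOE	EAS
APOE:snp2	1	1002000	G	A	-0.56409	0.0266872	3.62878e-99	0.196619	APOE	EAS
APOE:snp3	1	1003000	A	G	0.364475	0.028978	2.80159e-36	0.840628	APOE	EAS
PICALM:snp0	2	1000000	A	G	0.167068	0.0212904	4.25684e-15	0.44	PICALM	EAS
PICALM:snp1	2	1001000	G	A	-0.138141	0.0326586	2.33858e-05	0.119838	PICALM	EAS
PICALM:snp2	2	1002000	A	G	0.0602162	0.0215894	0.0052845	0.40707	PICALM	EAS
GBA1:snp0	3	1000000	A	G	0.0514982	0.060581	0.395285	0.0315	GBA1	EAS
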