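variant_id	chrom	pos	effect_allele	other_allele	beta	se	p_value	eaf	locus	ancestry
APOE:snp0	1	1000000	A	G	0.524468	0.0323631	4.59512e-59	0.192023	APOE	AFR
APOE:snp1	1	1001000	A	G	0.75903	0.0283938	1.98717e-157	0.21	APOE	AFR
APOE:snp2	1	1002000	G	A	-0.546592	0.0316381	7.08423e-67	0.796069	APOE	AFR
APOE:snp3	1	1003000	A	G	0.273125	0.0256831	2.06018e-26	0.439619	APOE	AFR
PICALM:snp0	2	1000000	A	G	0.192215	0.0273117	1.95279e-12	0.3	PICALM	AFR
PICALM:snp1	2	1001000	A	G	0.109994	0.0256603	1.81459e-05	0.443361	PICALM	AFR
PICALM:snp2	2	1002000	A	G	0.0952703	0.0255408	0.000191388	0.470097	PICALM	AFR
GBA1:snp0	3	1000000	A	G	0.488654	0.0451721	2.84128e-27	0.0826538	GBA1	AFR
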