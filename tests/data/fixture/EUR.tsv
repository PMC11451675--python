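variant_id	chrom	pos	effect_allele	other_allele	beta	se	p_value	eaf	locus	ancestry
APOE:snp0	1	1000000	A	G	0.608648	0.0191664	2.6178e-221	0.837476	APOE	EUR
APOE:snp1	1	1001000	A	G	0.96126	0.0176645	5e-308	0.15	APOE	EUR
APOE:snp2	1	1002000	A	G	0.447745	0.0141438	6.15631e-220	0.507726	APOE	EUR
APOE:snp3	1	1003000	A	G	0.358453	0.0182937	1.7274e-85	0.182834	APOE	EUR
PICALM:snp0	2	1000000	G	A	-0.177645	0.0145865	4.03531e-34	0.64	PICALM	EUR
PICALM:snp1	2	1001000	G	A	-0.0768048	0.0179152	1.80999e-05	0.806944	PICALM	EUR
PICALM:snp2	2	1002000	A	G	0.0380673	0.0143447	0.00796014	0.583724	PICALM	EUR
GBA1:snp0	3	1000000	A	G	0.0340912	0.049351	0.489698	0.020975	GBA1	EUR
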