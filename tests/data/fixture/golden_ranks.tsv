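locus	ancestry	par	rank
APOE	AFR	0.192639	1
APOE	AMR	0.100669	1
APOE	EAS	0.154268	1
APOE	EUR	0.195008	1
PICALM	AFR	0.0597786	2
PICALM	AMR	0.0604695	2
PICALM	EAS	0.0740803	2
PICALM	EUR	0.065407	2
GBA1	AFR	0.0495036	3
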