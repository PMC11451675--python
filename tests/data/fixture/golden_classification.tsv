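locus	classification
APOE	universal
PICALM	universal
GBA1	single
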