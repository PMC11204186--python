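# synthetic gene-table fixture emulating the cross-vertebrate gene-order
# comparison of the six-gene HERC2/OCA2 panel; coordinates are constructed
# (human is hg19-like), not extracted from a genome assembly.
chr3	7899999	8010697	ATP10A	0	-
chr3	8418899	8556616	GABRB3	0	-
chr3	8612803	8662296	GABRA5	0	+
chr3	8675540	9012708	GABRG3	0	+
chr3	9145696	9352386	OCA2	0	-
chr3	9359395	9486063	HERC2	0	-
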