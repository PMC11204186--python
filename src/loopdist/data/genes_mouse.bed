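# synthetic gene-table fixture emulating the cross-vertebrate gene-order
# comparison of the six-gene HERC2/OCA2 panel; coordinates are constructed
# (human is hg19-like), not extracted from a genome assembly.
chr7	55923859	56134972	HERC2	0	+
chr7	56146653	56491137	OCA2	0	+
chr7	56712784	57274729	GABRG3	0	-
chr7	57296803	57379292	GABRA5	0	-
chr7	57472937	57702465	GABRB3	0	+
chr7	58382802	58567298	ATP10A	0	+
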