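# synthetic gene-table fixture emulating the cross-vertebrate gene-order
# comparison of the six-gene HERC2/OCA2 panel; coordinates are constructed
# (human is hg19-like), not extracted from a genome assembly.
chr10	1149999	1214573	ATP10A	0	-
chr10	1452691	1533026	GABRB3	0	-
chr10	1565801	1594673	GABRA5	0	+
chr10	1602398	1799080	GABRG3	0	+
chr10	1876655	1997225	OCA2	0	-
chr10	2001313	2075203	HERC2	0	-
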