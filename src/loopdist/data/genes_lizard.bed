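# synthetic gene-table fixture emulating the cross-vertebrate gene-order
# comparison of the six-gene HERC2/OCA2 panel; coordinates are constructed
# (human is hg19-like), not extracted from a genome assembly.
chr2	12399999	12501472	ATP10A	0	-
chr2	12875657	13001898	GABRB3	0	-
chr2	13053402	13098772	GABRA5	0	+
chr2	13110912	13419982	GABRG3	0	+
chr2	13541888	13731354	OCA2	0	-
chr2	13737778	13853891	HERC2	0	-
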