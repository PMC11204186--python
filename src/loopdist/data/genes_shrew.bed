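# synthetic gene-table fixture emulating the cross-vertebrate gene-order
# comparison of the six-gene HERC2/OCA2 panel; coordinates are constructed
# (human is hg19-like), not extracted from a genome assembly.
scaffold_7	4199999	4347596	ATP10A	0	-
scaffold_7	4891865	5075488	GABRB3	0	-
scaffold_7	5150404	5216395	GABRA5	0	+
scaffold_7	5234054	5683610	GABRG3	0	+
scaffold_7	5860928	6136515	OCA2	0	-
scaffold_7	6145860	6314750	HERC2	0	-
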