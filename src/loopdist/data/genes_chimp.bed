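# synthetic gene-table fixture emulating the cross-vertebrate gene-order
# comparison of the six-gene HERC2/OCA2 panel; coordinates are constructed
# (human is hg19-like), not extracted from a genome assembly.
chr15	26060859	26245355	ATP10A	0	-
chr15	26925692	27155220	GABRB3	0	-
chr15	27248865	27331354	GABRA5	0	+
chr15	27353428	27915373	GABRG3	0	+
chr15	28137020	28481504	OCA2	0	-
chr15	28493185	28704298	HERC2	0	-
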