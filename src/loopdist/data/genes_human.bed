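# synthetic gene-table fixture emulating the cross-vertebrate gene-order
# comparison of the six-gene HERC2/OCA2 panel; coordinates are constructed
# (human is hg19-like), not extracted from a genome assembly.
chr15	25923859	26108355	ATP10A	0	-
chr15	26788692	27018220	GABRB3	0	-
chr15	27111865	27194354	GABRA5	0	+
chr15	27216428	27778373	GABRG3	0	+
chr15	28000020	28344504	OCA2	0	-
chr15	28356185	28567298	HERC2	0	-
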