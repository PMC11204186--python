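# synthetic gene-table fixture emulating the cross-vertebrate gene-order
# comparison of the six-gene HERC2/OCA2 panel; coordinates are constructed
# (human is hg19-like), not extracted from a genome assembly.
chr6	23599999	23683023	ATP10A	0	-
chr6	23989174	24092462	GABRB3	0	-
chr6	24134602	24171722	GABRA5	0	+
chr6	24181655	24434531	GABRG3	0	+
chr6	24534271	24689290	OCA2	0	-
chr6	24694546	24789547	HERC2	0	-
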