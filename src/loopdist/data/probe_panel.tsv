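number	name	chrom	start	end	role
1	RP11-339C21	chr15	25540816	25708423	anchor_proximal
2	RP11-299F22	chr15	26450149	26643939	loop_interior
3	RP11-39L5	chr15	27604108	27745105	loop_interior
4	RP11-640H21	chr15	27894428	28091240	anchor_proximal
5	RP11-142A11	chr15	28042426	28192499	anchor_proximal
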