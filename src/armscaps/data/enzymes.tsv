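# Restriction enzyme table: tab-separated name, IUPAC recognition, top-strand cut offset.
# AluI cuts AG^CT (offset 2); EcoRI cuts G^AATTC (offset 1). Extend freely.
name	recognition	cut_offset
AluI	AGCT	2
EcoRI	GAATTC	1
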