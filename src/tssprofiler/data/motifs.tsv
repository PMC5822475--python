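# Core fly promoter elements: name, IUPAC consensus, strand-oriented window
# relative to the TSS (offset_start, offset_end; negative = upstream).
# Windows are 50 nt and centred on each element's expected location; users
# may supply their own table in the same format.
TATA	TATAWAAR	-50	0
INR	TCAKTY	-25	25
TCT	TCTTTC	-25	25
DPE	RGWYVT	0	50
MTE	CSARCSSA	0	50
PB	KCGRWCG	0	50
GAGA	GAGAGAG	-250	0
DRE	WATCGATW	-250	0
Ebox	CACGTG	-250	0
BREu	SSRCGCC	-50	0
Ohler1	YGGTCACACTR	-100	0
Ohler6	KTYRGTATWTTT	-100	0
Ohler7	CAKCNCTR	-100	0
DCE1	CTTC	0	50
DCE3	AGC	0	50
Motif8	AWCAGCTGWT	-250	0
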