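# DR-beta residues at positions 37 and 86 per DRB1 allele.
# Curated from the IMGT/HLA protein alignment (release 3.11.0-era numbering).
allele	pos37	pos86
DRB1*01:01	S	G
DRB1*01:02	S	G
DRB1*01:03	S	G
DRB1*01:07	S	G
DRB1*03:01	N	V
DRB1*04:01	Y	G
DRB1*04:02	Y	V
DRB1*04:04	Y	V
DRB1*07:01	F	G
DRB1*08:01	Y	G
DRB1*09:01	N	G
DRB1*10:01	Y	V
DRB1*11:01	Y	V
DRB1*11:04	Y	V
DRB1*12:01	L	G
DRB1*13:01	N	V
DRB1*13:02	N	V
DRB1*13:03	Y	V
DRB1*13:05	Y	G
DRB1*14:02	N	V
DRB1*15:01	S	V
DRB1*15:02	S	V
DRB1*16:01	S	V
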