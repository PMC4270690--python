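# KIR-ligand epitope assignment for HLA-B (Bw4/Bw6) and HLA-C (C1/C2),
# plus MICA transmembrane microsatellite class (MICA5.1 = A5.1, e.g. MICA*008).
allele	epitope
B*07:02	Bw6
B*08:01	Bw6
B*13:02	Bw4
B*15:01	Bw6
B*18:01	Bw6
B*27:05	Bw4
B*35:01	Bw6
B*40:01	Bw6
B*44:02	Bw4
B*44:03	Bw4
B*51:01	Bw4
B*57:01	Bw4
C*01:02	C1
C*02:02	C2
C*03:03	C1
C*03:04	C1
C*04:01	C2
C*05:01	C2
C*06:02	C2
C*07:01	C1
C*07:02	C1
C*08:02	C1
C*12:03	C1
C*15:02	C2
C*16:01	C1
MICA*002	other
MICA*004	other
MICA*008	MICA5.1
MICA*009	other
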