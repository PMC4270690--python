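# Serotype collation map for HLA-A and HLA-B. Patterns are two-digit
# allele groups unless a four-digit split serotype is needed (B62/B60/B61).
pattern	serotype
A*01	A1
A*02	A2
A*03	A3
A*11	A11
A*23	A23
A*24	A24
A*25	A25
A*29	A29
A*30	A30
A*32	A32
A*33	A33
A*68	A68
B*07	B7
B*08	B8
B*13	B13
B*18	B18
B*27	B27
B*35	B35
B*44	B44
B*51	B51
B*54	B54
B*57	B57
B*15:01	B62
B*40:01	B60
B*40:02	B61
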