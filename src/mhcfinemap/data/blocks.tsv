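# DRB1-DQB1 haplotype block grouping rules. Patterns are exact four-digit
# alleles or two-digit groups; the three 13:XX rows collate all non-13:01
# DRB1*13 alleles paired with any DQB1*06 into one block.
drb1_pattern	dqb1_pattern	block
DRB1*03:01	DQB1*02:01	DRB1*03:01-DQB1*02:01
DRB1*13:01	DQB1*06:03	DRB1*13:01-DQB1*06:03
DRB1*04	DQB1*03	DRB1*04-DQB1*03
DRB1*07:01	DQB1*03:03	DRB1*07:01-DQB1*03:03
DRB1*13:02	DQB1*06	DRB1*13:XX-DQB1*06
DRB1*13:03	DQB1*06	DRB1*13:XX-DQB1*06
DRB1*13:05	DQB1*06	DRB1*13:XX-DQB1*06
DRB1*15:01	DQB1*06:02	DRB1*15:01-DQB1*06:02
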