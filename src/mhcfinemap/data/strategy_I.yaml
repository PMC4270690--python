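# Conditional strategy I: start from the class-I anchor of the AH8.1-like
# conserved haplotype (B*08), then greedily condition on the top remaining
# signal until nothing is left below the family-wise threshold.
name: strategy-I
steps:
  - "B*08"
  - top_remaining
  - top_remaining
  - top_remaining
  - top_remaining
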