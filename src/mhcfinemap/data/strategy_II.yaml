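# Conditional strategy II: start from the most significant classical HLA
# allele (the DRB3*01:01 analog, shared across two risk haplotypes).
name: strategy-II
steps:
  - "DRB3*01:01"
  - top_remaining
  - top_remaining
  - top_remaining
  - top_remaining
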