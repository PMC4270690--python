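# Conditional strategy III: start from the top amino-acid variable
# (Asparagine at DR-beta position 37).
name: strategy-III
steps:
  - Asn37
  - top_remaining
  - top_remaining
  - top_remaining
  - top_remaining
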