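# SYNTHETIC PLACEHOLDER — EQ-5D-3L utility values were not published.
# The 3L scenarios ship structure-only: replace the nulls below with the
# 3L-scored utilities (same layout as the default EQ-5D-5L block) to run them.
no_stroke:
  TAVI: [null, null, null, null]
  SAVR: [null, null, null, null]
post_stroke: [null, null, null, null]
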