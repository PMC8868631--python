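# Default motif configuration for the N6mA machinery screen.
#
# Patterns use bracket residue classes ([DNSH]PP[WFY]); X in a class means
# any residue.  Variants are literal strings of the same length.
motif_I:
  pattern: "[AG][X][AG][X][AG]"
  variants: []
motif_IV:
  pattern: "[DNSH]PP[WFY]"
  variants: ["EPPV", "NIPY", "NLPY"]
alkbh:
  fe_distal_gap: [10, 80]
  akg_gaps: [[1, 60], [1, 60], [1, 30]]
aromatic_cage:
  allowed: ["F", "W", "Y", "L"]
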