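# Key residues and domain partition, canonical human numbering.
# Positions the source literature names are exact; the full
# cysteine lists are a synthetic completion to the printed counts
# (25 catalytic + C-terminal, of which 18 in the V-domain).
gene_id: PCSK9
late_truncation_threshold: 681
analysis_start: 31
catalytic_triad: {186: D, 226: H, 386: S}
oxyanion: {317: N}
cysteines:
  catalytic: [223, 255, 323, 358, 363, 378, 428]
  v_domain: [457, 477, 486, 527, 534, 562, 588, 600, 601, 608, 617, 623, 635, 654, 661, 668, 672, 679]
domains:
  signal_peptide: [1, 30]
  prodomain: [31, 152]
  catalytic: [153, 452]
  v_domain: [453, 682]
  c_terminal_tail: [683, 692]
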