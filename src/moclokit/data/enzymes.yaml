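# Type IIs enzyme definitions (REBASE geometry). The assembly chemistry only
# assumes: recognition on one strand, a fixed spacer, then a staggered cut
# leaving a 4-nt 5' overhang. Swap or extend freely.
enzymes:
  BsaI:
    recognition: GGTCTC   # GGTCTC(1/5)
    spacer_len: 1
    overhang_len: 4
  BpiI:
    recognition: GAAGAC   # GAAGAC(2/6), isoschizomer of BbsI
    spacer_len: 2
    overhang_len: 4
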