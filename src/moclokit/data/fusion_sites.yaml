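# Fusion-site grammar. Fs1..Fs4 order promoter/CDS/terminator within one
# transcription unit; FsA..FsI order transcription units on a multigene
# plasmid (9 boundary sites -> up to 8 units).
#
# Only three words are fixed by the published system: Fs2=CATG (carries the
# start codon ATG), Fs3=GCTT and FsB=CCGG. The remaining words below are
# NON-CANONICAL generated defaults: pairwise distinct, never another site's
# reverse complement, and palindromic only where the fixed words already are
# (CATG and CCGG self-pair; see validate_fusion_site_set).
bb2_sites:
  Fs1: GGAG   # non-canonical default
  Fs2: CATG   # fixed: ends in the ATG start codon (palindromic)
  Fs3: GCTT   # fixed: CDS-terminator junction
  Fs4: CGCT   # non-canonical default
bb3_sites:
  FsA: TGCC   # non-canonical default
  FsB: CCGG   # fixed: unit1-unit2 junction (palindromic)
  FsC: ACTG   # non-canonical default
  FsD: GTCA   # non-canonical default
  FsE: CAGA   # non-canonical default
  FsF: TGGA   # non-canonical default
  FsG: CTTC   # non-canonical default
  FsH: AAGG   # non-canonical default
  FsI: ATCC   # non-canonical default
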