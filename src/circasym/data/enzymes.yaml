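# Restriction enzyme definitions (standard REBASE conventions):
#   site       recognition sequence, IUPAC letters allowed
#   cut_offset top-strand cut position, nt from the site start
ApaI:
  site: GGGCCC
  cut_offset: 5
SwaI:
  site: ATTTAAAT
  cut_offset: 4
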