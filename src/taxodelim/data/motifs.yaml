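# Landmark motif definitions for 16S-23S ITS dissection.
#
# The conserved-domain convention (D1-D1', D2, D3, boxA, D4 plus the
# variable V2/boxB/V3 regions) anchors dissection on short conserved
# motifs; the sequences below are synthetic stand-ins with the canonical
# lengths (D2 = 12, D3 = 5, boxA = 12, D4 = 7 bp) and are meant to be
# overridden with organism-specific motifs for real data.
#
# max_mismatches applies per motif (ungapped approximate matching).
d2:
  sequence: CAGCGTGGCGGA
  max_mismatches: 1
d3:
  sequence: CTATA
  max_mismatches: 1
boxa:
  sequence: ACTCCTTCTTGG
  max_mismatches: 1
d4:
  sequence: GTGCTAT
  max_mismatches: 1
# The boxB helix opens with AGCA and closes with its complement TGCT
# (UGCU in RNA); the V3 helix opens with GTC and closes with GAC.
boxb_start:
  sequence: AGCA
  max_mismatches: 0
boxb_end:
  sequence: TGCT
  max_mismatches: 0
v3_start:
  sequence: GTC
  max_mismatches: 0
v3_end:
  sequence: GAC
  max_mismatches: 0
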