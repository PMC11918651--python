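# ACTA1 transcript architecture (versioned configuration).
#
# Exon/intron lengths are in genomic bp; the coding sequence starts 12 nt
# into exon 2, so exon 1 plus the first 12 nt of exon 2 form the 5' UTR.
# The codon spanning the exon 6/7 junction is attributed to exon 6, which
# is why exon 6 is credited with a fractional 60.67 coded amino acids.
version: 1
gene: ACTA1
protein_length: 377          # residues, initiator Met included
coding_length: 1134          # nt, stop codon included (377 * 3 + 3)
coding_start_offset_in_exon2: 12
exons:                       # genomic lengths, bp
  1: 91
  2: 141
  3: 325
  4: 162
  5: 192
  6: 182
  7: 398
introns:
  1: 876
  2: 106
  3: 124
  4: 84
  5: 91
  6: 78
# Coding nucleotides contributed by each exon (exon 7's 398 bp are mostly
# 3' UTR; only 144 nt are coding, stop codon included).
coding_nt:
  2: 129
  3: 325
  4: 162
  5: 192
  6: 182
  7: 144
nmd_escape_window_nt: 50     # 3'-most stretch of the penultimate exon that escapes NMD
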