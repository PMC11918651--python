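# Methods

## Gene model and coordinates

The *ACTA1* transcript model ships as a versioned YAML config
(`src/actinterp/data/acta1_exon_model.yaml`). Exon/intron genomic
lengths are 91/876/141/106/325/124/162/84/192/91/182/78/398 bp; the
coding sequence (1134 nt including the stop codon, 377 residues)
starts 12 nt into exon 2 — the only offset consistent with exon 2
coding 43 residues (129 nt of its 141 bp) and with the conventional
`c.` names of the known splice variants (c.455-2, c.617-5, c.809-9 …).
Derived coding spans are exon 2 = c.1–129, exon 3 = c.130–454,
exon 4 = c.455–616, exon 5 = c.617–808, exon 6 = c.809–990,
exon 7 = c.991–1134. The codon split across the exon 6/7 junction is
attributed to exon 6, which is why exon 6 is credited 60.67 coded
residues and the per-exon coded-residue numbers are fractional.

Protein residues are stored in HGVS numbering (initiator Met = 1).
Legacy (mature-protein) numbering differs by exactly the two cleaved
N-terminal residues: HGVS = legacy + 2. The two schemes are never
inferred from context — a label is treated as legacy only when tagged
as such — because published usage is inconsistent enough that silent
inference would corrupt records.

**NMD escape.** Premature termination codons in the last exon, or in
the 3'-most `nmd_window_nt` nucleotides of the penultimate exon,
are predicted to evade nonsense-mediated decay. The window is a
configurable constant defaulting to 50 nt (the boundary is c.941),
reflecting the usual "50-nucleotide rule"; the biological boundary is
approximate, so the constant is exposed rather than hard-coded.

**Stop-loss extension.** Given a 3'UTR sequence starting immediately
after the reference stop, the engine counts codons to the first
in-frame stop. On the real *ACTA1* 3'UTR this yields the documented
47-residue C-terminal extension; the reference UTR is an optional
external data file, so tests exercise the scan on synthetic UTRs with
known stop positions (cross-checked against Biopython translation).

## Knowledgebase

Variants are keyed by `(isoform, canonical cDNA string)` when a cDNA
change is known, else by the canonical protein string — variants are
counted at the nucleotide level, since distinct nucleotide changes can
produce the same substitution. Duplicate rows merge their report
lists; conflicting prior classifications are retained and resolved
only by the evidence rules. HGVS parsing is a purpose-built subset
parser covering substitutions, del/dup/ins, frameshifts,
stop-loss/start-loss extensions and synonymous changes as they occur
in actin variant databases; it is not a general HGVS implementation.
Population records carry summed v2-like and v3-like allele counts, a
homozygote count (validated against allele count), and optionally the
lower bound of the oldest carrier's age bracket.

## Paralog mapping

The six actins are aligned with a star alignment anchored on the first
sequence: global pairwise alignments (Needleman–Wunsch via Biopython's
`PairwiseAligner`, BLOSUM62, gap open 10 / extend 1) merged on the
anchor's coordinates. At ≥ 93% pairwise identity the alignment is
insensitive to these parameters; they are fixed for determinism.
Column conservation uses the Clustal strong/weak substitution groups
(`*` identical, `:` conserved, `.` semiconserved). Prior reports are
projected onto alignment columns and bucketed by confidence tier:
cardiac (ACTC1, which differs from ACTA1 at only 4 residues), smooth
muscle (ACTA2/ACTG2), cytoplasmic (ACTB/ACTG1).

## Evidence rules

Seventeen rules (R1–R17) plus the sliding-window hotspot rule
(SW-PM1). Key thresholds, all in one `RuleConfig`:

| parameter | default | meaning |
|---|---|---|
| `cadd_pathogenic` | 20 | CADD PHRED floor for PP3 (with AlphaMissense agreement) |
| `cadd_high_confidence` | 30 | annotated as high-confidence in the rationale |
| `spliceai_advisory` | 0.2 | advisory flag only, never an ACMG code |
| `spliceai_pathogenic` | 0.5 | PP3 (splice) |
| `nmd_window_nt` | 50 | penultimate-exon escape window |
| `pp1_*_meioses` | 3/5/7 | segregation tiers (supporting/moderate/strong) |
| `bs1_age_cutoff` | 50 | oldest-carrier age bracket must exceed this for BS1 |
| `pp4_phenotypes` | NEM, IRM | high-specificity phenotype set |

Design choices where the underlying criteria leave room:

- **Provisional items.** Rules marked low-confidence emit items at one
  strength level below the code's default and flag them `provisional`;
  the combiner's strict mode drops them. Tier weighting composes with
  this: PS1 from ACTC1 is firm/strong, from smooth-muscle actins
  moderate/provisional, from cytoplasmic actins
  supporting/provisional (strengths clamp at supporting).
- **At most one PM1** (strongest wins, firm beats provisional) across
  R12, R17 and SW-PM1 — how these interact is not specified anywhere,
  so the conservative "single strongest hotspot claim" reading is
  used. The same dedup is applied to PM5 (an ACTA1 same-residue match
  and a paralog-projected one are the same kind of evidence and are
  not double-counted).
- **BS1 requires explicit age data**: population presence without an
  oldest-carrier age bracket > 50 years only removes PM2; it never
  asserts BS1, because age is frequently unavailable and the "> 50
  years" criterion is an exemplar, not a guarantee.
- **R4 second hits are flagged, not resolved**: phasing is out of
  scope, so the recessive track emits `check_second_allele` instead of
  auto-resolving compound heterozygosity.
- **Hotspot regions** are the maximal residue intervals delimited by
  *purely benign* missense residues (all reports B/LB). A residue
  carrying both benign and pathogenic missense reports does not
  delimit; it stays inside a region and contributes to both counts, so
  such regions can only qualify through the ≥ 3-pathogenic-variant
  path. This is the reading that makes the dual criterion ("no benign
  and ≥ 1 pathogenic" OR "≥ 3 pathogenic") non-vacuous. No fixed
  window length is assumed — "sliding window" is honored through
  delimiter-based maximal regions.

Missing inputs skip their rules rather than failing, and removing an
input only ever removes the items of rules consuming it (verified as a
property test).

## Combining

Items combine by their *assigned* strength class (ClinGen convention —
a downgraded PS counts as one PM, an upgraded PP1 as one PS) through
the standard ACMG/AMP rules. Two very-strong items are treated as
Pathogenic, the sequence-variant-interpretation refinement of the
original table. When both a pathogenic and a benign rule fire the
verdict is VUS with a conflict flag. The implementation is verified
exhaustively against an independently written pattern-lookup
transcription of the combining table over all evidence multisets of
size ≤ 5. Classification always runs both inheritance tracks; the
dominant and recessive tracks differ only in the null-variant rule
(PVS1 recessive by default, dominant only on NMD escape) and the
population rule (recessive PM2 = no homozygotes).

## Summary statistics

Percentages round half-up at the printed precision (1 decimal for
breakdowns, 0 for shares, 2 for o/e ratios); denominators are always
the facet's own total or an explicit argument. Published breakdowns
whose printed rounding is inconsistent with their own numerators
(e.g. 365/391 printed as 93.3 where half-up gives 93.4) are not
reproduced — the module computes from counts, not from printed
percentages. Per-exon *percentage* columns of the published
distribution table use an underivable denominator (≈ 335, not the 343
total) and are likewise out of scope; per-exon counts are supported.

## Synthetic data

The generator's defaults are the study conditions of the curated
*ACTA1* set: 391 P/LP variants (340 missense over 154 distinct
residues, 18 frameshift, 13 nonsense, 9 canonical splice, 6 in-frame,
3 stop-loss, 2 start-loss), 147 B/LB (one missense at the poorly
conserved residue 5 whose substituted amino acid is the wild-type
ACTC1 residue; the rest synonymous/intronic, all population-present in
older carriers), 13 VUS with ambiguous in-silico support, 88% of
dominant variants confirmed de novo, ~42% of recessive nulls present
as population heterozygotes, pathogenic-missense CADD ≥ 20 and benign
CADD < 20, 65 population-only missense residues of which 19 overlap
the pathogenic set, and per-isoform paralog report counts
(154/79/86/30/100/78) whose ACTA1-projected union covers 345 residues.

Synthetic paralog sequences reproduce the family's *structure* — all
substitutions drawn from a shared 26-position variable pool so every
pairwise identity stays ≥ 93%, exactly 4 ACTA1/ACTC1 differences, one
and two N-terminal deletions for ACTG2 and the cytoplasmic actins —
but they are random sequences, not the real actins. Consequently,
passing tests demonstrate that the alignment, mapping, evidence and
combining machinery behave correctly on data with the documented
statistical and structural properties; they do not validate
biological conclusions about specific real residues. Real sequences
and report snapshots drop in through the same FASTA/TSV interfaces.
Generation is fully deterministic: one `random.Random(seed)` stream,
sorted iteration orders, byte-identical output for a fixed spec.

## Problem sizes and determinism

Tests run the full default bundle (≈ 550 distinct variants) through
classification — a few seconds of CPU. The combiner equivalence check
enumerates all 3 003 evidence multisets of size ≤ 5. Hypothesis
profiles are registered derandomized so runs are reproducible.

## Known limitations

- Genomic (chr1) coordinates, liftover, and full-transcript sequence
  management are out of scope; the reference 3'UTR is an optional
  input.
- The HGVS parser covers the subset of nomenclature seen in actin
  databases; exotic descriptions (ranged substitutions, complex
  delins with breakpoint uncertainty) are rejected as row-level
  errors rather than parsed.
- Functional-assay codes (PS3/BS3) pass through only if supplied by
  the caller; mosaic allele balance is carried as an annotation, never
  interpreted.
- VarSome-style aggregate scoring is not replicated; the engine
  implements the gene-specific criteria directly.
- Cross-paralog evidence assumes the star alignment is correct; at
  ≥ 93% identity this is safe, but the module should not be reused for
  divergent protein families without a proper progressive aligner.
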