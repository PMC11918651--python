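# actinterp

Gene-specific ACMG/AMP variant interpretation for the human actin
family, centred on *ACTA1* (skeletal-muscle alpha-actin).

## The problem

*ACTA1* encodes a 377-residue protein that forms the core of the
sarcomeric thin filament. It is one of the most missense-constrained
genes known (gnomAD missense o/e ≈ 0.21), essentially every reported
pathogenic missense variant is dominant and usually de novo, null
variants are recessive unless they escape nonsense-mediated decay
(NMD), and the six human actin paralogs (ACTA1, ACTC1, ACTA2, ACTG2,
ACTB, ACTG1) are ≥ 93% identical to each other — so pathogenicity
evidence transfers between homologous residues. Generic ACMG/AMP
classification handles none of this well: *ACTA1* has no discrete
functional domains for the hotspot criterion (PM1), two residue
numbering schemes circulate in the literature (HGVS counts from Met1;
legacy numbering counts from the mature protein, offset by the two
cleaved N-terminal residues), and automated classifiers ignore de novo
reports and cross-paralog evidence.

`actinterp` is a reusable engine for this setting, aimed at curators
and diagnostic scientists working on actinopathies:

- **`gene_model`** — the *ACTA1* exon architecture (exons 2–7 code
  43/108.3/54/64/60.7/47 residues), `c.` position localization,
  legacy ↔ HGVS residue conversion (legacy + 2 = HGVS), the NMD-escape
  window (last 50 nt of exon 6 + exon 7, i.e. c.941 onward), and the
  stop-loss C-terminal extension (codon scan of a supplied 3'UTR).
- **`knowledgebase`** — TSV/VCF/JSON ingestion of variant reports
  (HGMD/LOVD/ClinVar-style), gnomAD-like population records and
  precomputed scores (CADD, SpliceAI, AlphaMissense), normalized and
  deduplicated at the cDNA level, with the lookup queries the evidence
  rules need.
- **`paralog_map`** — deterministic global alignment of the six actins
  (BLOSUM62, affine gaps), residue mapping between isoforms, Clustal
  `*`/`:`/`.` column conservation, and per-column aggregation of prior
  reports into confidence tiers (ACTC1 > ACTA2/ACTG2 > ACTB/ACTG1).
- **`evidence`** — seventeen gene-specific rules (R1–R17) emitting
  ACMG codes (PS2/PM6 for de novo, PVS1 for stop-loss SNVs and
  recessive nulls, PP2 from missense constraint, PP3 from CADD ≥ 20 +
  AlphaMissense or SpliceAI ≥ 0.5, PM2/BS1/BS2 from population data,
  PS1/PM5 transferred from paralogs, tier-weighted) plus a
  density-based hotspot PM1: benign missense residues delimit candidate
  regions, and a region qualifies if it is benign-free with ≥ 1
  pathogenic variant, or contains ≥ 3 pathogenic variants.
- **`combiner`** — the standard ACMG/AMP combining rules over
  strength-adjusted items, run under both dominant and recessive
  inheritance assumptions, with a strict mode that drops
  low-confidence (provisional) items.
- **`summary_stats`** — consequence/inheritance/exon breakdowns,
  residue-coverage fractions, o/e constraint ratios, population
  overlap, cross-actin residue unions.
- **`fixtures`** — a seeded generator that plants a ground-truth
  variant spectrum (by default mirroring the published *ACTA1*
  curation: 391 P/LP variants, 340 of them missense over 154 residues,
  one benign missense, recessive nulls, 147 B/LB) so the entire
  pipeline is testable offline. Its actin sequences are synthetic but
  reproduce the family's structure (≥ 93% identity, exactly 4
  ACTA1/ACTC1 differences); real FASTA records drop in unchanged.

## Worked example

```
$ actinterp convert-numbering --legacy 256
legacy 256 = HGVS 258
```

The mature protein lacks the two cleaved N-terminal residues, so the
historically reported "p.Arg256His" is p.Arg258His in HGVS numbering —
the conversion that routinely confuses actin variant lookups.

```
$ actinterp locate c.617-5
Intron4

$ actinterp fixtures generate --seed 7 --out fx
$ actinterp map-residue ACTA1:258 --to ACTB --fasta fx/actins.fasta
ACTA1:258 -> ACTB:256

$ actinterp stats --kb fx/kb.tsv --facet consequence
frameshift      18      4.6
inframe_del     6       1.5
missense        340     87.0
nonsense        13      3.3
splice_acceptor 4       1.0
splice_donor    5       1.3
start_loss      2       0.5
stop_loss       3       0.8
```

The splice-acceptor variant c.617-5C>A sits in intron 4; ACTB is two
residues shorter than ACTA1 at the N-terminus, so ACTA1 residue 258
is ACTB residue 256; and of the 391 planted P/LP variants, 340
(87.0%) are missense — the generator's default spectrum.

Classifying a de novo missense variant from the bundle against the
knowledgebase, annotations and population table:

```
$ actinterp classify query.tsv --kb fx/kb.tsv --annot fx/annot.tsv --popn fx/popn.tsv
```

prints one JSON object per variant and track; for the c.16C>T
(p.Pro6His) example the dominant track reports verdict `P` with
evidence `PS2` (confirmed de novo), `PM1` (qualifying hotspot region
6–377), `PM2` (absent from population data), `PM5` (different
pathogenic change at the residue), and `PP2/PP3/PP4/PP5` supporting
items — the characteristic pattern that makes de novo *ACTA1* missense
variants at least likely pathogenic.

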