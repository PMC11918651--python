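"""Variant knowledgebase: ingestion, normalization, and lookup queries.

Holds three kinds of tables, mirroring how curated actin variant data is
distributed:

* a **variant table** (``kb`` dialect) — one row per source report of a
  variant in any of the six actin genes, with prior classifications;
* a **population table** (``popn`` dialect) — gnomAD-style allele and
  homozygote counts with an optional oldest-carrier age;
* an **annotation table** (``annot`` dialect) — precomputed in-silico
  scores (CADD PHRED, SpliceAI max delta, AlphaMissense class).

Rows are normalized on load (HGVS strings canonicalized, legacy protein
labels shifted to Met1-anchored numbering) and deduplicated by variant
key: ``(isoform, canonical cDNA string)`` when a cDNA change is present,
else ``(isoform, canonical protein string)`` — variants are counted at
the cDNA level, so two nucleotide changes producing the same amino-acid
substitution remain distinct.  Conflicting prior classifications are
retained; resolution is the evidence rules' job, not the loader's.
"""

from __future__ import annotations

import json
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import gene_model
from .nomenclature import (
    CdnaChange,
    HgvsParseError,
    ProteinChange,
    parse_cdna_change,
    parse_protein_change,
    CONSEQUENCE_KINDS,
)

__all__ = [
    "ISOFORM_LENGTHS",
    "PriorReport",
    "PopulationRecord",
    "AnnotationBundle",
    "VariantRecord",
    "Knowledgebase",
    "load_variant_table",
]

#: protein lengths of the six human actins (initiator Met included)
ISOFORM_LENGTHS = {
    "ACTA1": 377,
    "ACTC1": 377,
    "ACTA2": 377,
    "ACTG2": 376,
    "ACTB": 375,
    "ACTG1": 375,
}

CLASSIFICATIONS = ("P", "LP", "VUS", "LB", "B")
SOURCES = ("HGMD", "LOVD", "ClinVar", "literature")

_SPLICE_KINDS = {"splice_donor", "splice_acceptor", "splice_region", "intronic"}


@dataclass
class PriorReport:
    source: str
    classification: str
    isoform: str
    protein_change: ProteinChange | None = None
    cdna_change: CdnaChange | None = None
    n_cases: int = 1
    de_novo_count: int = 0

    def __post_init__(self):
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(
                f"classification {self.classification!r} not in {CLASSIFICATIONS}"
            )

    @property
    def is_pathogenic(self) -> bool:
        return self.classification in ("P", "LP")

    @property
    def is_benign(self) -> bool:
        return self.classification in ("B", "LB")


@dataclass
class PopulationRecord:
    key: tuple[str, str]
    ac_v2: int = 0
    ac_v3: int = 0
    hom_count: int = 0
    oldest_age: float | None = None  # lower bound of the oldest carrier's age bracket
    residue: int | None = None  # affected protein residue, when the change is coding

    @property
    def allele_count(self) -> int:
        return self.ac_v2 + self.ac_v3


@dataclass
class AnnotationBundle:
    cadd_phred: float | None = None
    spliceai_max_delta: float | None = None
    alphamissense_class: str | None = None  # likely_benign | ambiguous | likely_pathogenic
    population: PopulationRecord | None = None

    def __post_init__(self):
        if self.spliceai_max_delta is not None and not 0 <= self.spliceai_max_delta <= 1:
            raise ValueError("SpliceAI delta must be within [0, 1]")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError("CADD PHRED must be non-negative")


@dataclass
class VariantRecord:
    isoform: str
    cdna_change: CdnaChange | None = None
    protein_change: ProteinChange | None = None
    consequence: str = ""
    inheritance: str = "unknown"  # dominant | recessive | unknown
    de_novo: str = "unknown"  # confirmed | assumed | inherited | unknown
    allele_balance: float | None = None
    phenotypes: tuple[str, ...] = ()
    reports: list[PriorReport] = field(default_factory=list)
    annotations: AnnotationBundle | None = None
    region: str = ""  # exon/intron label from the gene model

    def __post_init__(self):
        if self.consequence and self.consequence not in CONSEQUENCE_KINDS:
            raise ValueError(
                f"unknown consequence {self.consequence!r}; accepted kinds: "
                f"{', '.join(CONSEQUENCE_KINDS)}"
            )
        if self.protein_change is not None:
            length = ISOFORM_LENGTHS.get(self.isoform)
            # the stop codon itself (residue length+1) is addressable by
            # stop-loss changes such as p.Ter378GlnextTer47
            upper = (length or 0) + (1 if self.protein_change.kind == "stop_loss" else 0)
            if length and not 1 <= self.protein_change.hgvs_residue <= upper:
                raise ValueError(
                    f"residue {self.protein_change.hgvs_residue} outside "
                    f"{self.isoform} (length {length})"
                )

    @property
    def key(self) -> tuple[str, str]:
        if self.cdna_change is not None:
            return (self.isoform, str(self.cdna_change))
        if self.protein_change is not None:
            return (self.isoform, str(self.protein_change))
        raise ValueError("variant has neither cDNA nor protein change")

    @property
    def is_null(self) -> bool:
        """Whether the variant is a putative loss-of-function (null) allele."""
        if self.consequence in ("nonsense", "frameshift", "start_loss"):
            return True
        if self.consequence in ("splice_donor", "splice_acceptor"):
            # canonical +/-1,2 positions
            if self.cdna_change is None:
                return True
            off = self.cdna_change.start.offset
            return off != 0 and abs(off) <= 2
        return False


def _parse_protein_field(text: str) -> ProteinChange | None:
    if not text or text in ("", ".", "NA"):
        return None
    return parse_protein_change(text)


def _parse_cdna_field(text: str) -> CdnaChange | None:
    if not text or text in ("", ".", "NA"):
        return None
    return parse_cdna_change(text)


class Knowledgebase:
    """Indexed store of variant records, prior reports and annotations."""

    def __init__(self):
        self.records: dict[tuple[str, str], VariantRecord] = {}
        self.population: dict[tuple[str, str], PopulationRecord] = {}
        self.errors: list[str] = []

    # ------------------------------------------------------------------ load

    def add_record(self, record: VariantRecord) -> VariantRecord:
        """Insert *record*, merging report lists on duplicate keys."""
        key = record.key
        existing = self.records.get(key)
        if existing is None:
            self.records[key] = record
            if record.cdna_change is not None and record.isoform == "ACTA1":
                try:
                    record.region = gene_model.exon_of(record.cdna_change.start)
                except gene_model.GeneModelError:
                    record.region = ""
            return record
        for rep in record.reports:
            if rep not in existing.reports:
                existing.reports.append(rep)
        if existing.annotations is None:
            existing.annotations = record.annotations
        for attr in ("inheritance", "de_novo"):
            if getattr(existing, attr) == "unknown":
                setattr(existing, attr, getattr(record, attr))
        if not existing.phenotypes:
            existing.phenotypes = record.phenotypes
        return existing

    def load_variants(self, path: str | Path) -> "Knowledgebase":
        df = _read_tsv(path, _KB_COLUMNS, "kb")
        for i, row in df.iterrows():
            try:
                protein = _parse_protein_field(row.get("protein_change", ""))
                cdna = _parse_cdna_field(row.get("cdna_change", ""))
                if protein is None and cdna is None:
                    raise HgvsParseError("row has neither cDNA nor protein change")
                reports = []
                if row.get("source"):
                    reports.append(
                        PriorReport(
                            source=row["source"],
                            classification=row.get("classification", "VUS") or "VUS",
                            isoform=row["isoform"],
                            protein_change=protein,
                            cdna_change=cdna,
                            n_cases=int(row.get("n_cases") or 1),
                            de_novo_count=int(row.get("de_novo_count") or 0),
                        )
                    )
                record = VariantRecord(
                    isoform=row["isoform"],
                    cdna_change=cdna,
                    protein_change=protein,
                    consequence=row.get("consequence", "") or "",
                    inheritance=row.get("inheritance", "unknown") or "unknown",
                    de_novo=row.get("de_novo", "unknown") or "unknown",
                    allele_balance=_opt_float(row.get("allele_balance")),
                    phenotypes=tuple(
                        p.strip() for p in str(row.get("phenotypes", "") or "").split(";") if p.strip()
                    ),
                    reports=reports,
                )
                self.add_record(record)
            except (HgvsParseError, ValueError, gene_model.GeneModelError) as exc:
                self.errors.append(f"{Path(path).name} row {i + 2}: {exc}")
        return self

    def load_population(self, path: str | Path) -> "Knowledgebase":
        df = _read_tsv(path, _POPN_COLUMNS, "popn")
        for i, row in df.iterrows():
            try:
                key = _row_key(row)
                prot = _parse_protein_field(row.get("protein_change", ""))
                rec = PopulationRecord(
                    key=key,
                    ac_v2=int(row.get("ac_v2") or 0),
                    ac_v3=int(row.get("ac_v3") or 0),
                    hom_count=int(row.get("hom_count") or 0),
                    oldest_age=_opt_float(row.get("oldest_age")),
                    residue=prot.hgvs_residue if prot is not None else None,
                )
                if rec.hom_count > rec.allele_count // 2:
                    raise ValueError(
                        f"homozygote count {rec.hom_count} exceeds allele count "
                        f"{rec.allele_count} / 2"
                    )
                self.population[key] = rec
            except (HgvsParseError, ValueError) as exc:
                self.errors.append(f"{Path(path).name} row {i + 2}: {exc}")
        return self

    def load_annotations(self, path: str | Path) -> "Knowledgebase":
        df = _read_tsv(path, _ANNOT_COLUMNS, "annot")
        for i, row in df.iterrows():
            try:
                key = _row_key(row)
                bundle = AnnotationBundle(
                    cadd_phred=_opt_float(row.get("cadd_phred")),
                    spliceai_max_delta=_opt_float(row.get("spliceai_max_delta")),
                    alphamissense_class=row.get("alphamissense_class") or None,
                    population=self.population.get(key),
                )
                if key in self.records:
                    self.records[key].annotations = bundle
                else:
                    self.errors.append(
                        f"{Path(path).name} row {i + 2}: no variant with key {key}"
                    )
            except (HgvsParseError, ValueError) as exc:
                self.errors.append(f"{Path(path).name} row {i + 2}: {exc}")
        return self

    def load_vcf(self, path: str | Path, config: dict | None = None) -> "Knowledgebase":
        """Ingest a minimal single-sample VCF.

        HGVS strings are read from INFO fields named in *config*
        (defaults: ``HGVSC``, ``HGVSP``, ``CONSEQ``); genotype fields are
        ignored.
        """
        import pysam

        config = config or {}
        cdna_field = config.get("cdna_info_field", "HGVSC")
        prot_field = config.get("protein_info_field", "HGVSP")
        conseq_field = config.get("consequence_info_field", "CONSEQ")
        isoform = config.get("isoform", "ACTA1")
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                try:
                    cdna = rec.info.get(cdna_field)
                    prot = rec.info.get(prot_field)
                    self.add_record(
                        VariantRecord(
                            isoform=isoform,
                            cdna_change=_parse_cdna_field(cdna or ""),
                            protein_change=_parse_protein_field(prot or ""),
                            consequence=rec.info.get(conseq_field, "") or "",
                        )
                    )
                except (HgvsParseError, ValueError) as exc:
                    self.errors.append(f"{Path(path).name} {rec.chrom}:{rec.pos}: {exc}")
        return self

    # --------------------------------------------------------------- queries

    def same_change_reports(
        self, isoform: str, protein_change: ProteinChange | str
    ) -> list[PriorReport]:
        """All prior reports of exactly this amino-acid change in *isoform*."""
        if isinstance(protein_change, str):
            protein_change = parse_protein_change(protein_change)
        target = str(protein_change)
        out = []
        for rec in self.records.values():
            if rec.isoform != isoform or rec.protein_change is None:
                continue
            if str(rec.protein_change) == target:
                out.extend(rec.reports)
        return out

    def same_residue_reports(
        self,
        isoform: str,
        hgvs_residue: int,
        excluding_change: ProteinChange | str | None = None,
    ) -> list[PriorReport]:
        """Reports of a *different* change at the same residue in *isoform*."""
        excl = (
            str(parse_protein_change(excluding_change))
            if isinstance(excluding_change, str)
            else (str(excluding_change) if excluding_change else None)
        )
        out = []
        for rec in self.records.values():
            pc = rec.protein_change
            if rec.isoform != isoform or pc is None:
                continue
            if pc.hgvs_residue != hgvs_residue:
                continue
            if excl is not None and str(pc) == excl:
                continue
            out.extend(rec.reports)
        return out

    def population_presence(
        self, variant: VariantRecord | tuple[str, str]
    ) -> tuple[str, float | None]:
        """Classify population presence: absent / present_het / present_hom.

        Unions the v2-like and v3-like allele counts; the second element
        is the oldest carrier's age-bracket lower bound, if recorded.
        """
        key = variant.key if isinstance(variant, VariantRecord) else variant
        rec = self.population.get(key)
        if rec is None or rec.allele_count == 0:
            return ("absent", None)
        status = "present_hom" if rec.hom_count > 0 else "present_het"
        return (status, rec.oldest_age)

    # ------------------------------------------------------------- summaries

    def benign_missense_residues(self, isoform: str = "ACTA1") -> set[int]:
        """Residues where every reported missense classification is B/LB."""
        benign, pathogenic_or_vus = set(), set()
        for rec in self.records.values():
            pc = rec.protein_change
            if rec.isoform != isoform or pc is None or pc.kind != "missense":
                continue
            for rep in rec.reports:
                if rep.is_benign:
                    benign.add(pc.hgvs_residue)
                else:
                    pathogenic_or_vus.add(pc.hgvs_residue)
        return benign - pathogenic_or_vus

    def missense_residues(self, isoform: str = "ACTA1", classifications=("P", "LP")) -> set[int]:
        out = set()
        for rec in self.records.values():
            pc = rec.protein_change
            if rec.isoform != isoform or pc is None or pc.kind != "missense":
                continue
            if any(rep.classification in classifications for rep in rec.reports):
                out.add(pc.hgvs_residue)
        return out

    def population_missense_residues(self, isoform: str = "ACTA1") -> set[int]:
        """Protein residues touched by any population-table record."""
        return {
            p.residue
            for key, p in self.population.items()
            if key[0] == isoform and p.residue is not None and p.allele_count > 0
        }

    # ----------------------------------------------------------- round trips

    def to_json(self) -> str:
        def rec_dict(rec: VariantRecord) -> dict:
            return {
                "isoform": rec.isoform,
                "cdna_change": str(rec.cdna_change) if rec.cdna_change else None,
                "protein_change": str(rec.protein_change) if rec.protein_change else None,
                "consequence": rec.consequence,
                "inheritance": rec.inheritance,
                "de_novo": rec.de_novo,
                "allele_balance": rec.allele_balance,
                "phenotypes": sorted(rec.phenotypes),
                "region": rec.region,
                "reports": sorted(
                    (
                        {
                            "source": r.source,
                            "classification": r.classification,
                            "isoform": r.isoform,
                            "protein_change": str(r.protein_change) if r.protein_change else None,
                            "cdna_change": str(r.cdna_change) if r.cdna_change else None,
                            "n_cases": r.n_cases,
                            "de_novo_count": r.de_novo_count,
                        }
                        for r in rec.reports
                    ),
                    key=lambda d: (d["source"], d["classification"]),
                ),
                "annotations": (
                    {
                        "cadd_phred": rec.annotations.cadd_phred,
                        "spliceai_max_delta": rec.annotations.spliceai_max_delta,
                        "alphamissense_class": rec.annotations.alphamissense_class,
                    }
                    if rec.annotations
                    else None
                ),
            }

        payload = {
            "records": {
                f"{k[0]}|{k[1]}": rec_dict(v) for k, v in sorted(self.records.items())
            },
            "population": {
                f"{k[0]}|{k[1]}": {
                    "ac_v2": p.ac_v2,
                    "ac_v3": p.ac_v3,
                    "hom_count": p.hom_count,
                    "oldest_age": p.oldest_age,
                    "residue": p.residue,
                }
                for k, p in sorted(self.population.items())
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Knowledgebase":
        payload = json.loads(text)
        kb = cls()
        for key, d in payload["records"].items():
            isoform, _ = key.split("|", 1)
            rec = VariantRecord(
                isoform=d["isoform"],
                cdna_change=_parse_cdna_field(d["cdna_change"] or ""),
                protein_change=_parse_protein_field(d["protein_change"] or ""),
                consequence=d["consequence"],
                inheritance=d["inheritance"],
                de_novo=d["de_novo"],
                allele_balance=d["allele_balance"],
                phenotypes=tuple(d["phenotypes"]),
                reports=[
                    PriorReport(
                        source=r["source"],
                        classification=r["classification"],
                        isoform=r["isoform"],
                        protein_change=_parse_protein_field(r["protein_change"] or ""),
                        cdna_change=_parse_cdna_field(r["cdna_change"] or ""),
                        n_cases=r["n_cases"],
                        de_novo_count=r["de_novo_count"],
                    )
                    for r in d["reports"]
                ],
            )
            if d.get("annotations"):
                rec.annotations = AnnotationBundle(**d["annotations"])
            kb.add_record(rec)
        for key, p in payload.get("population", {}).items():
            isoform, change = key.split("|", 1)
            kb.population[(isoform, change)] = PopulationRecord(key=(isoform, change), **p)
        # reattach population references
        for key, rec in kb.records.items():
            if rec.annotations is not None:
                rec.annotations.population = kb.population.get(key)
        return kb

    # -------------------------------------------------------------- validate

    def validate(self) -> list[str]:
        """Consistency warnings: exon assignment vs consequence, score ranges."""
        out = []
        for key, rec in self.records.items():
            if rec.cdna_change is not None and rec.consequence:
                intronic = rec.cdna_change.intronic
                if rec.consequence in ("intronic", "splice_donor", "splice_acceptor"):
                    if not intronic:
                        out.append(f"{key}: consequence {rec.consequence} but exonic cDNA")
                elif rec.consequence not in _SPLICE_KINDS and intronic:
                    out.append(f"{key}: consequence {rec.consequence} but intronic cDNA")
        return out


_KB_COLUMNS = [
    "isoform", "cdna_change", "protein_change", "consequence", "inheritance",
    "de_novo", "allele_balance", "phenotypes", "source", "classification",
    "n_cases", "de_novo_count",
]
_POPN_COLUMNS = ["isoform", "cdna_change", "protein_change", "ac_v2", "ac_v3", "hom_count", "oldest_age"]
_ANNOT_COLUMNS = ["isoform", "cdna_change", "protein_change", "cadd_phred", "spliceai_max_delta", "alphamissense_class"]


def _read_tsv(path: str | Path, expected: list[str], dialect: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        _warnings.warn(
            f"{Path(path).name} ({dialect}): ignoring unknown columns {unknown}",
            stacklevel=3,
        )
        df = df.drop(columns=unknown)
    missing_key = {"isoform"} - set(df.columns)
    if missing_key:
        raise ValueError(f"{path}: required column(s) missing: {sorted(missing_key)}")
    return df


def _row_key(row) -> tuple[str, str]:
    cdna = _parse_cdna_field(row.get("cdna_change", ""))
    if cdna is not None:
        return (row["isoform"], str(cdna))
    prot = _parse_protein_field(row.get("protein_change", ""))
    if prot is None:
        raise HgvsParseError("row has neither cDNA nor protein change")
    return (row["isoform"], str(prot))


def _opt_float(value) -> float | None:
    if value is None or value == "" or value == ".":
        return None
    return float(value)


def load_variant_table(path: str | Path, dialect: str = "kb") -> Knowledgebase:
    """Load a TSV of the given dialect into a fresh knowledgebase."""
    kb = Knowledgebase()
    if dialect == "kb":
        return kb.load_variants(path)
    if dialect == "popn":
        return kb.load_population(path)
    if dialect == "annot":
        raise ValueError("annotation tables must be loaded into an existing knowledgebase")
    raise ValueError(f"unknown dialect {dialect!r}")
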