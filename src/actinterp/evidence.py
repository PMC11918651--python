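"""ACTA1-specific ACMG evidence rules and the hotspot (PM1) region model.

Seventeen gene-specific adaptations of the ACMG/AMP criteria are
implemented as rules R1-R17, plus a sliding-window hotspot model
(SW-PM1).  Each rule inspects one slice of the inputs — the variant
itself, its annotation bundle, the knowledgebase, cross-paralog column
evidence, or family data — and emits :class:`EvidenceItem` objects.  A
rule whose required input is missing is skipped, never failed.

Rules marked low-confidence in the underlying criteria set are emitted
as *provisional* items at one strength level below the code's default;
the combiner can drop them in strict mode.

The hotspot model replaces the domain-based PM1 definition, which does
not suit ACTA1 (no discrete functional domains, near-uniform missense
constraint): benign missense residues partition the protein into
candidate regions, and a region qualifies when it contains no benign
variant and at least one pathogenic variant, or three or more pathogenic
variants regardless of benign content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import gene_model
from .knowledgebase import ISOFORM_LENGTHS, Knowledgebase, VariantRecord, AnnotationBundle
from .paralog_map import ColumnEvidence

__all__ = [
    "RuleConfig",
    "EvidenceItem",
    "FamilyEvidence",
    "HotspotRegion",
    "Evaluation",
    "STRENGTH_RANK",
    "compute_hotspots",
    "region_qualifies",
    "evaluate",
]

STRENGTH_RANK = {
    "supporting": 1,
    "moderate": 2,
    "strong": 3,
    "very_strong": 4,
    "stand_alone": 4,
}

#: default strength class of each ACMG code family
DEFAULT_STRENGTH = {
    "PVS": "very_strong",
    "PS": "strong",
    "PM": "moderate",
    "PP": "supporting",
    "BA": "stand_alone",
    "BS": "strong",
    "BP": "supporting",
}

VALID_CODES = (
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + ["BA1"]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 8)]
)


def code_family(code: str) -> str:
    return code.rstrip("0123456789")


def default_strength(code: str) -> str:
    return DEFAULT_STRENGTH[code_family(code)]


@dataclass
class RuleConfig:
    """Tunable thresholds for the evidence rules (one config, one place)."""

    cadd_pathogenic: float = 20.0
    cadd_high_confidence: float = 30.0
    spliceai_advisory: float = 0.2
    spliceai_pathogenic: float = 0.5
    nmd_window_nt: int = 50
    pp1_supporting_meioses: int = 3
    pp1_moderate_meioses: int = 5
    pp1_strong_meioses: int = 7
    bs1_age_cutoff: float = 50.0
    pp4_phenotypes: tuple[str, ...] = ("nemaline myopathy", "intranuclear rod myopathy")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "pp4_phenotypes" in data:
            data["pp4_phenotypes"] = tuple(data["pp4_phenotypes"])
        return cls(**data)


@dataclass(frozen=True)
class EvidenceItem:
    """One ACMG evidence code with its assigned strength and provenance."""

    code: str
    strength: str
    rule_id: str
    confidence: str = "firm"  # firm | provisional
    rationale: str = ""

    def __post_init__(self):
        if self.code not in VALID_CODES:
            raise ValueError(f"unknown ACMG code {self.code!r}")
        if self.strength not in STRENGTH_RANK:
            raise ValueError(f"unknown strength {self.strength!r}")

    @property
    def benign_side(self) -> bool:
        return self.code.startswith("B")


@dataclass(frozen=True)
class FamilyEvidence:
    """Family-level observations for one variant."""

    de_novo: str = "none"  # confirmed | assumed | none
    meioses: int = 0  # informative segregating meioses

    def __post_init__(self):
        if self.meioses < 0:
            raise ValueError("meioses must be >= 0")


@dataclass(frozen=True)
class HotspotRegion:
    """A candidate mutational-hotspot interval in HGVS residue coordinates."""

    start: int
    end: int
    pathogenic_count: int
    benign_count: int
    qualifies: bool

    def __contains__(self, residue: int) -> bool:
        return self.start <= residue <= self.end


@dataclass
class Evaluation:
    """Outcome of evaluating one variant: evidence items plus workflow flags."""

    items: list[EvidenceItem] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def codes(self) -> set[str]:
        return {item.code for item in self.items}

    def __iter__(self):
        return iter(self.items)


# ----------------------------------------------------------------- hotspots


def region_qualifies(pathogenic_count: int, benign_count: int) -> bool:
    """Dual criterion: benign-free with >=1 pathogenic, or >=3 pathogenic."""
    return (benign_count == 0 and pathogenic_count >= 1) or pathogenic_count >= 3


def compute_hotspots(kb: Knowledgebase, isoform: str = "ACTA1") -> list[HotspotRegion]:
    """Partition the protein into candidate PM1 regions.

    Residues whose reported missense variants are *exclusively* B/LB act
    as delimiters; the maximal intervals between them are the candidate
    regions.  A residue carrying both benign and pathogenic missense
    reports does not delimit — it stays inside a region and contributes
    to both counts, in which case the region can only qualify through
    the three-pathogenic-variant path.
    """
    length = ISOFORM_LENGTHS[isoform]
    delimiters = sorted(kb.benign_missense_residues(isoform))

    path_at: dict[int, int] = {}
    benign_at: dict[int, int] = {}
    for rec in kb.records.values():
        pc = rec.protein_change
        if rec.isoform != isoform or pc is None or pc.kind != "missense":
            continue
        if any(rep.is_pathogenic for rep in rec.reports):
            path_at[pc.hgvs_residue] = path_at.get(pc.hgvs_residue, 0) + 1
        elif any(rep.is_benign for rep in rec.reports):
            benign_at[pc.hgvs_residue] = benign_at.get(pc.hgvs_residue, 0) + 1

    bounds = [0] + delimiters + [length + 1]
    regions = []
    for lo, hi in zip(bounds, bounds[1:]):
        start, end = lo + 1, hi - 1
        if start > end:
            continue
        path = sum(n for r, n in path_at.items() if start <= r <= end)
        benign = sum(n for r, n in benign_at.items() if start <= r <= end)
        regions.append(
            HotspotRegion(start, end, path, benign, region_qualifies(path, benign))
        )
    return regions


# ----------------------------------------------------------------- evaluate


def evaluate(
    variant: VariantRecord,
    annotations: AnnotationBundle | None = None,
    kb: Knowledgebase | None = None,
    paralog_evidence: ColumnEvidence | None = None,
    family: FamilyEvidence | None = None,
    track: str = "dominant",
    hotspots: list[HotspotRegion] | None = None,
    config: RuleConfig | None = None,
) -> Evaluation:
    """Run every applicable rule against one variant.

    *track* selects the inheritance assumption (``dominant`` or
    ``recessive``), which changes only the null-variant rule (R4) and
    the population-absence rule (R10).  Missing inputs silently skip the
    rules that consume them.
    """
    if track not in ("dominant", "recessive"):
        raise ValueError(f"unknown track {track!r}")
    cfg = config or RuleConfig()
    if annotations is None and variant.annotations is not None:
        annotations = variant.annotations
    out = Evaluation()
    pc = variant.protein_change
    pm1_candidates: list[EvidenceItem] = []
    pm5_candidates: list[EvidenceItem] = []

    # R1 — phenotype specificity
    specific = {p.lower() for p in cfg.pp4_phenotypes}
    if any(p.lower() in specific for p in variant.phenotypes):
        out.items.append(
            EvidenceItem("PP4", "supporting", "R1", rationale="highly specific phenotype")
        )

    # R2 — de novo status, else segregation
    de_novo = family.de_novo if family is not None else (
        variant.de_novo if variant.de_novo in ("confirmed", "assumed") else "none"
    )
    if de_novo == "confirmed":
        out.items.append(EvidenceItem("PS2", "strong", "R2", rationale="confirmed de novo"))
    elif de_novo == "assumed":
        out.items.append(
            EvidenceItem("PM6", "moderate", "R2", rationale="assumed de novo (parentage unconfirmed)")
        )
    elif family is not None and family.meioses >= cfg.pp1_supporting_meioses:
        if family.meioses >= cfg.pp1_strong_meioses:
            strength = "strong"
        elif family.meioses >= cfg.pp1_moderate_meioses:
            strength = "moderate"
        else:
            strength = "supporting"
        out.items.append(
            EvidenceItem(
                "PP1", strength, "R2",
                rationale=f"segregation across {family.meioses} informative meioses",
            )
        )

    # R3 — stop-loss single-nucleotide changes
    if variant.consequence == "stop_loss":
        if variant.cdna_change is None or variant.cdna_change.is_snv:
            out.items.append(
                EvidenceItem(
                    "PVS1", "very_strong", "R3",
                    rationale="stop-loss SNV appends a fixed C-terminal extension",
                )
            )
        else:
            out.flags.append("stop_loss_indel_requires_review")

    # R4 — null variants: recessive by default, dominant only on NMD escape
    if variant.is_null:
        if track == "recessive":
            out.items.append(
                EvidenceItem("PVS1", "very_strong", "R4", rationale="null variant, recessive track")
            )
            out.flags.append("check_second_allele")
        else:
            escapes = False
            if (
                variant.consequence in ("nonsense", "frameshift")
                and variant.cdna_change is not None
                and variant.cdna_change.start.offset == 0
            ):
                try:
                    escapes = gene_model.nmd_escape(variant.cdna_change.start)
                except gene_model.GeneModelError:
                    escapes = False
            if escapes:
                out.items.append(
                    EvidenceItem(
                        "PVS1", "very_strong", "R4",
                        rationale="premature termination escapes NMD; dominant candidate",
                    )
                )
            else:
                out.flags.append("null_variant_recessive_candidate")

    # R5 — splice prediction
    if annotations is not None and annotations.spliceai_max_delta is not None:
        delta = annotations.spliceai_max_delta
        if delta >= cfg.spliceai_pathogenic:
            out.items.append(
                EvidenceItem("PP3", "supporting", "R5", rationale=f"SpliceAI delta {delta:.2f}")
            )
        elif delta >= cfg.spliceai_advisory:
            out.flags.append("possible_splice_altering")

    # R6 — missense constraint
    if variant.consequence == "missense":
        out.items.append(
            EvidenceItem("PP2", "supporting", "R6", rationale="gene under extreme missense constraint")
        )

    # R7 — in-silico consensus for missense
    if (
        variant.consequence == "missense"
        and annotations is not None
        and annotations.cadd_phred is not None
        and annotations.alphamissense_class is not None
    ):
        cadd = annotations.cadd_phred
        am = annotations.alphamissense_class
        if cadd >= cfg.cadd_pathogenic and am == "likely_pathogenic":
            conf = "high confidence" if cadd > cfg.cadd_high_confidence else "concordant"
            out.items.append(
                EvidenceItem("PP3", "supporting", "R7", rationale=f"CADD {cadd:.1f}, AlphaMissense pathogenic ({conf})")
            )
        elif cadd < cfg.cadd_pathogenic and am != "likely_pathogenic":
            out.flags.append("benign_leaning_in_silico")

    # R8/R9 — prior reports in ACTA1 (same gene); variants without a
    # protein-level description (intronic, splice) match on the cDNA key
    if kb is not None and (pc is not None or variant.cdna_change is not None):
        if pc is not None:
            same = kb.same_change_reports(variant.isoform, pc)
        else:
            rec = kb.records.get(variant.key)
            same = rec.reports if rec is not None else []
        if any(rep.is_pathogenic for rep in same):
            out.items.append(
                EvidenceItem("PP5", "supporting", "R8", rationale="same change previously reported P/LP")
            )
        if any(rep.is_benign for rep in same):
            out.items.append(
                EvidenceItem("BS2", "strong", "R11", rationale="same change previously reported B/LB")
            )
        residue_reports = (
            kb.same_residue_reports(variant.isoform, pc.hgvs_residue, pc)
            if pc is not None and pc.kind == "missense"
            else []
        )
        # PM5 is about alternative amino-acid substitutions, so truncating
        # changes that happen to start at the same residue do not count
        if any(
            rep.is_pathogenic
            and rep.protein_change is not None
            and rep.protein_change.kind == "missense"
            for rep in residue_reports
        ):
            pm5_candidates.append(
                EvidenceItem("PM5", "moderate", "R9", rationale="different P/LP change at the same residue")
            )

    # R10 — population presence
    if kb is not None and kb.population is not None and (
        variant.cdna_change is not None or pc is not None
    ):
        status, oldest = kb.population_presence(variant)
        if status == "absent":
            out.items.append(
                EvidenceItem("PM2", "moderate", "R10", rationale="absent from population datasets")
            )
        else:
            if track == "recessive" and status != "present_hom":
                out.items.append(
                    EvidenceItem("PM2", "moderate", "R10", rationale="no homozygotes in population datasets")
                )
            if oldest is not None and oldest > cfg.bs1_age_cutoff:
                out.items.append(
                    EvidenceItem(
                        "BS1", "strong", "R10",
                        rationale=f"population carrier in age bracket > {cfg.bs1_age_cutoff:.0f} y",
                    )
                )

    # R12-R17 — cross-paralog evidence
    if paralog_evidence is not None and pc is not None and variant.consequence == "missense":
        pe = paralog_evidence
        if pe.conservation == "identical":
            pm1_candidates.append(
                EvidenceItem(
                    "PM1", "supporting", "R12", confidence="provisional",
                    rationale="residue completely conserved across all actins",
                )
            )
        # same change in a paralog -> PS1, tier-weighted
        ps1 = None
        if pe.tier_reports("same_change", "cardiac"):
            ps1 = EvidenceItem("PS1", "strong", "R14", rationale="same change P/LP in ACTC1")
        elif pe.tier_reports("same_change", "smooth"):
            ps1 = EvidenceItem(
                "PS1", "moderate", "R13", confidence="provisional",
                rationale="same change P/LP in a smooth-muscle actin",
            )
        elif pe.tier_reports("same_change", "cytoplasmic"):
            ps1 = EvidenceItem(
                "PS1", "supporting", "R13", confidence="provisional",
                rationale="same change P/LP in a cytoplasmic actin",
            )
        if ps1 is not None:
            out.items.append(ps1)
        # different change at the homologous residue -> PM5, tier-weighted
        if pe.tier_reports("same_residue", "cardiac"):
            pm5_candidates.append(
                EvidenceItem("PM5", "moderate", "R16", rationale="different P/LP change at the ACTC1 residue")
            )
        elif pe.tier_reports("same_residue", "smooth"):
            pm5_candidates.append(
                EvidenceItem(
                    "PM5", "supporting", "R15", confidence="provisional",
                    rationale="different P/LP change at the homologous smooth-muscle residue",
                )
            )
        elif pe.tier_reports("same_residue", "cytoplasmic"):
            pm5_candidates.append(
                EvidenceItem(
                    "PM5", "supporting", "R15", confidence="provisional",
                    rationale="different P/LP change at the homologous cytoplasmic residue",
                )
            )
        # R17 — recurrently mutated, fully conserved, clean column
        if (
            pe.conservation == "identical"
            and len(pe.distinct_plp_changes) >= 2
            and not pe.benign_at_column
        ):
            clean = True
            if kb is not None:
                if pc.hgvs_residue in kb.population_missense_residues(variant.isoform):
                    clean = False
                if kb.same_change_reports(variant.isoform, pc) and any(
                    rep.is_benign for rep in kb.same_change_reports(variant.isoform, pc)
                ):
                    clean = False
            if clean:
                pm1_candidates.append(
                    EvidenceItem(
                        "PM1", "moderate", "R17",
                        rationale=">=2 distinct P/LP changes at a fully conserved residue",
                    )
                )

    # SW-PM1 — sliding-window hotspot model
    if hotspots and pc is not None and variant.consequence == "missense":
        for region in hotspots:
            if region.qualifies and pc.hgvs_residue in region:
                pm1_candidates.append(
                    EvidenceItem(
                        "PM1", "moderate", "SW-PM1",
                        rationale=f"within qualifying hotspot region {region.start}-{region.end}",
                    )
                )
                break

    # at most one PM1 / PM5: keep the strongest, firm beating provisional
    for candidates in (pm1_candidates, pm5_candidates):
        if candidates:
            best = max(
                candidates,
                key=lambda it: (STRENGTH_RANK[it.strength], it.confidence == "firm"),
            )
            out.items.append(best)
    return out
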