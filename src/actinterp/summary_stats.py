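"""Descriptive statistics over a variant knowledgebase.

Counts and ratios are reported the way curation papers print them:
percentages rounded half-up at a stated precision, observed/expected
(o/e) constraint ratios at two decimals, and explicit denominators
everywhere — a denominator is always the facet's own total or a caller
argument, never inferred.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .knowledgebase import ISOFORM_LENGTHS, Knowledgebase
from .paralog_map import IsoformAlignment

__all__ = [
    "ConstraintStats",
    "BreakdownTable",
    "round_half_up",
    "oe_ratio",
    "breakdown",
    "de_novo_share",
    "population_overlap",
    "cross_actin_residue_union",
]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConstraintStats:
    """Population-constraint summary: observed vs expected variant counts."""

    observed: float
    expected: float

    def __post_init__(self):
        if self.expected <= 0:
            raise ValueError("expected count must be > 0")

    @property
    def oe_ratio(self) -> float:
        return round_half_up(self.observed / self.expected, 2)


def oe_ratio(observed: float, expected: float) -> float:
    """Observed/expected ratio, half-up at 2 decimals (e.g. 55/260.9 -> 0.21)."""
    return ConstraintStats(observed, expected).oe_ratio


@dataclass
class BreakdownTable:
    """Category -> (count, percentage) with an explicit denominator."""

    facet: str
    denominator: int
    rows: dict[str, tuple[int, float]]

    def count(self, category: str) -> int:
        return self.rows.get(category, (0, 0.0))[0]

    def percentage(self, category: str) -> float:
        return self.rows.get(category, (0, 0.0))[1]


def _plp_records(kb: Knowledgebase, isoform: str):
    for rec in kb.records.values():
        if rec.isoform != isoform:
            continue
        if any(rep.is_pathogenic for rep in rec.reports):
            yield rec


def breakdown(
    kb: Knowledgebase,
    facet: str,
    isoform: str = "ACTA1",
    classifications: tuple[str, ...] = ("P", "LP"),
    decimals: int = 1,
) -> BreakdownTable:
    """Tabulate the knowledgebase along one facet.

    Facets: ``consequence`` and ``inheritance`` count variants;
    ``exon`` counts variants per exon/intron region; ``residues``
    returns the distinct residues carrying qualifying missense variants
    as a fraction of the protein length.
    """
    records = [
        rec
        for rec in kb.records.values()
        if rec.isoform == isoform
        and any(rep.classification in classifications for rep in rec.reports)
    ]
    if facet == "residues":
        residues = {
            rec.protein_change.hgvs_residue
            for rec in records
            if rec.protein_change is not None and rec.protein_change.kind == "missense"
        }
        length = ISOFORM_LENGTHS[isoform]
        pct = round_half_up(100.0 * len(residues) / length, decimals) if residues else 0.0
        return BreakdownTable(facet, length, {"residues": (len(residues), pct)})

    if facet == "consequence":
        keyfn = lambda rec: rec.consequence or "unspecified"
    elif facet == "inheritance":
        keyfn = lambda rec: rec.inheritance
    elif facet == "exon":
        keyfn = lambda rec: rec.region or "unlocalized"
    else:
        raise ValueError(f"unknown facet {facet!r}")

    counts: dict[str, int] = {}
    for rec in records:
        k = keyfn(rec)
        counts[k] = counts.get(k, 0) + 1
    total = sum(counts.values())
    rows = {
        k: (n, round_half_up(100.0 * n / total, decimals) if total else 0.0)
        for k, n in sorted(counts.items())
    }
    return BreakdownTable(facet, total, rows)


def de_novo_share(confirmed_de_novo: int, inherited: int) -> int:
    """Percentage of confirmed-origin dominant variants that arose de novo."""
    if confirmed_de_novo < 0 or inherited < 0:
        raise ValueError("counts must be non-negative")
    total = confirmed_de_novo + inherited
    if total == 0:
        raise ValueError("no variants with confirmed origin")
    return int(round_half_up(100.0 * confirmed_de_novo / total, 0))


def population_overlap(
    kb_pathogenic_residues: set[int], population_missense_residues: set[int]
) -> tuple[int, int | None]:
    """Overlap of population-observed missense residues with known
    pathogenic residues: (count, percentage of the population set)."""
    overlap = len(kb_pathogenic_residues & population_missense_residues)
    if not population_missense_residues:
        return (0, None)
    pct = int(round_half_up(100.0 * overlap / len(population_missense_residues), 0))
    return (overlap, pct)


def cross_actin_residue_union(
    paralog_reports,
    alignment: IsoformAlignment,
    reference: str = "ACTA1",
) -> int:
    """Distinct reference-projected residues with >=1 P/LP missense in any
    isoform (each residue counted once regardless of how many isoforms
    report it; residues gapped in the reference are not countable)."""
    residues: set[int] = set()
    for rep in paralog_reports:
        pc = rep.protein_change
        if pc is None or pc.kind != "missense" or not rep.is_pathogenic:
            continue
        if rep.isoform not in alignment.aligned:
            continue
        if rep.isoform == reference:
            residues.add(pc.hgvs_residue)
            continue
        mapped = alignment.map_residue(rep.isoform, pc.hgvs_residue, reference)
        if mapped is not None:
            residues.add(mapped)
    return len(residues)
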