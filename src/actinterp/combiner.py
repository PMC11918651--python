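"""ACMG/AMP evidence combination into the five-tier verdict.

Evidence items are counted by their *assigned* strength class, not the
default strength of their code (the ClinGen convention) — a PS-coded
item downgraded to moderate counts as one PM, a PP1 upgraded to strong
counts as one PS.  The standard combining rules then yield Pathogenic /
Likely pathogenic / VUS / Likely benign / Benign; when both a pathogenic
and a benign rule are satisfied the verdict is VUS with a conflict flag.

Two PVS-strength items together are treated as Pathogenic, following
the ClinGen sequence-variant-interpretation refinement of the original
combining table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .evidence import (
    EvidenceItem,
    Evaluation,
    FamilyEvidence,
    RuleConfig,
    compute_hotspots,
    evaluate,
)
from .knowledgebase import AnnotationBundle, Knowledgebase, VariantRecord
from .paralog_map import ColumnEvidence

__all__ = ["Classification", "combine", "classify_variant", "VERDICT_ORDER"]

#: benign-to-pathogenic ordering, for monotonicity comparisons
VERDICT_ORDER = {"B": 0, "LB": 1, "VUS": 2, "LP": 3, "P": 4}


@dataclass
class Classification:
    """Five-tier verdict with the evidence that produced it."""

    verdict: str  # P | LP | VUS | LB | B
    track: str = "dominant"
    items: list[EvidenceItem] = field(default_factory=list)
    provisional_included: bool = True
    conflict: bool = False
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "track": self.track,
            "conflict": self.conflict,
            "provisional_included": self.provisional_included,
            "flags": sorted(self.flags),
            "evidence": [
                {
                    "code": it.code,
                    "strength": it.strength,
                    "confidence": it.confidence,
                    "rule_id": it.rule_id,
                    "rationale": it.rationale,
                }
                for it in self.items
            ],
        }


def _counts(items: list[EvidenceItem]) -> tuple[int, int, int, int, int, int, int]:
    pvs = ps = pm = pp = ba = bs = bp = 0
    for it in items:
        if it.benign_side:
            if it.strength == "stand_alone":
                ba += 1
            elif it.strength == "strong":
                bs += 1
            else:
                bp += 1
        else:
            if it.strength == "very_strong":
                pvs += 1
            elif it.strength == "strong":
                ps += 1
            elif it.strength == "moderate":
                pm += 1
            else:
                pp += 1
    return pvs, ps, pm, pp, ba, bs, bp


def combine(items: list[EvidenceItem], mode: str = "default", track: str = "dominant") -> Classification:
    """Apply the ACMG/AMP combining rules to a set of evidence items.

    ``mode="strict"`` first drops provisional (low-confidence) items.
    """
    if mode not in ("default", "strict"):
        raise ValueError(f"unknown mode {mode!r}")
    used = [it for it in items if mode == "default" or it.confidence == "firm"]
    pvs, ps, pm, pp, ba, bs, bp = _counts(used)

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp >= 1) or pp >= 2))
        or pvs >= 2
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs >= 1 and pm >= 1)
        or (ps >= 1 and pm >= 1)
        or (ps >= 1 and pp >= 2)
        or pm >= 3
        or (pm >= 2 and pp >= 2)
        or (pm >= 1 and pp >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2

    path_verdict = "P" if pathogenic else ("LP" if likely_pathogenic else None)
    benign_verdict = "B" if benign else ("LB" if likely_benign else None)

    if path_verdict and benign_verdict:
        verdict, conflict = "VUS", True
    elif path_verdict:
        verdict, conflict = path_verdict, False
    elif benign_verdict:
        verdict, conflict = benign_verdict, False
    else:
        verdict, conflict = "VUS", False
    return Classification(
        verdict=verdict,
        track=track,
        items=used,
        provisional_included=(mode == "default"),
        conflict=conflict,
    )


def classify_variant(
    variant: VariantRecord,
    kb: Knowledgebase | None = None,
    annotations: AnnotationBundle | None = None,
    paralog_evidence: ColumnEvidence | None = None,
    family: FamilyEvidence | None = None,
    mode: str = "default",
    config: RuleConfig | None = None,
    hotspots=None,
) -> dict[str, Classification]:
    """Evaluate and combine under both inheritance tracks.

    Returns ``{"dominant": ..., "recessive": ...}``.  When the variant's
    inheritance is recorded, the matching track is the primary verdict;
    with unknown inheritance both tracks are equally reportable.
    """
    if hotspots is None and kb is not None:
        hotspots = compute_hotspots(kb, variant.isoform) if variant.isoform == "ACTA1" else []
    out: dict[str, Classification] = {}
    for track in ("dominant", "recessive"):
        ev: Evaluation = evaluate(
            variant,
            annotations=annotations,
            kb=kb,
            paralog_evidence=paralog_evidence,
            family=family,
            track=track,
            hotspots=hotspots,
            config=config,
        )
        cls = combine(ev.items, mode=mode, track=track)
        cls.flags = ev.flags
        out[track] = cls
    return out
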