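"""Synthetic data bundles with planted ground truth.

Generates everything the pipeline consumes — a variant knowledgebase,
annotation and population tables, six paralog protein sequences, and a
cross-actin report snapshot — with a known, planted classification for
every variant, so the whole engine is testable without any download.

The default :class:`FixtureSpec` emulates the published ACTA1 variant
spectrum: a missense-dominated P/LP set (340 variants over 154 distinct
residues), recessive null variants, a single benign missense at a
poorly conserved N-terminal residue, benign synonymous/intronic
variants seen in population data in older carriers, pathogenic missense
CADD scores above 20 and benign ones below, and per-isoform paralog
report counts whose ACTA1-projected union covers 345 of 377 residues.
Sequences are synthetic: they reproduce the family's *structure*
(pairwise identity >= 93%, exactly 4 ACTA1/ACTC1 differences, shorter
cytoplasmic isoforms) but are not the real actin sequences.

Generation is deterministic: the same seed yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .knowledgebase import ISOFORM_LENGTHS

__all__ = ["FixtureSpec", "FixtureError", "generate", "toy_paralogs"]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# conservative substitution partners (within Clustal strong groups) keep
# synthetic paralog columns looking like real actin alignment columns
_CONSERVATIVE = {
    "S": "TA", "T": "SA", "A": "ST", "N": "EQK", "E": "NQK", "Q": "NEK",
    "K": "NEQ", "H": "NY", "D": "NE", "R": "QK", "M": "ILV", "I": "MLV",
    "L": "MIV", "V": "MIL", "F": "MIL", "Y": "HF", "W": "FY", "C": "SA",
    "G": "SA", "P": "ST",
}

_PHENOTYPES = [
    ("nemaline myopathy", 0.74),
    ("congenital fibre type disproportion", 0.072),
    ("intranuclear rod myopathy", 0.043),
    ("fetal akinesia", 0.053),
    ("dilated cardiomyopathy", 0.053),
    ("distal myopathy", 0.039),
]

_AA3 = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr",
}

# exon boundaries in c. coordinates (first/last coding base per exon)
_EXON_STARTS = [130, 455, 617, 809, 991]
_EXON_ENDS = [129, 454, 616, 808, 990]


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Knobs of the generator; defaults mirror the curated spectrum."""

    seed: int = 0
    # pathogenic/likely pathogenic set
    n_plp_missense: int = 340
    n_plp_missense_residues: int = 154
    n_frameshift: int = 18
    n_nonsense: int = 13
    n_splice: int = 9
    n_inframe: int = 6
    n_stop_loss: int = 3
    n_start_loss: int = 2
    n_nmd_escape_frameshift: int = 1  # of n_frameshift, dominant via NMD escape
    # benign set
    n_benign_missense: int = 1
    n_benign_other: int = 146
    n_benign_high_spliceai: int = 5
    # uncertain set
    n_vus_missense: int = 13
    # behaviour
    de_novo_fraction: float = 0.88
    recessive_population_fraction: float = 0.42
    multi_source_fraction: float = 0.2
    # population-only missense residues and their overlap with P/LP residues
    n_popn_missense_residues: int = 65
    n_popn_overlap_residues: int = 19
    # paralog report snapshot: residues-with-P/LP per isoform, and the
    # target size of the ACTA1-projected union
    paralog_residue_counts: dict = field(
        default_factory=lambda: {
            "ACTA1": 154, "ACTC1": 79, "ACTA2": 86, "ACTG2": 30, "ACTB": 100, "ACTG1": 78,
        }
    )
    n_union_residues: int = 345

    def validate(self) -> None:
        for name, value in dataclasses.asdict(self).items():
            if isinstance(value, (int, float)) and name != "seed" and value < 0:
                raise FixtureError(f"{name} must be non-negative")
        if self.n_plp_missense < self.n_plp_missense_residues:
            raise FixtureError("fewer missense variants than planted residues")
        if self.n_plp_missense_residues + self.n_benign_missense + self.n_vus_missense > 370:
            raise FixtureError("planted residue sets exceed the protein length")
        if self.n_popn_overlap_residues > min(
            self.n_popn_missense_residues, self.n_plp_missense_residues
        ):
            raise FixtureError("overlap larger than its parent sets")
        if not self.n_plp_missense_residues <= self.n_union_residues <= 371:
            raise FixtureError("union residue count out of range")
        if self.n_nmd_escape_frameshift > self.n_frameshift:
            raise FixtureError("more NMD-escape frameshifts than frameshifts")


# ------------------------------------------------------------------ sequences


def _random_protein(rng: random.Random, length: int) -> str:
    seq = ["M", "C", "D"] + [rng.choice(_AA20) for _ in range(length - 3)]
    return "".join(seq[:length])


def _substitute(rng: random.Random, seq: str, positions: list[int]) -> str:
    out = list(seq)
    for pos in positions:  # 1-based
        orig = out[pos - 1]
        partners = _CONSERVATIVE.get(orig, "")
        out[pos - 1] = rng.choice(partners) if partners else rng.choice(
            [a for a in _AA20 if a != orig]
        )
    return "".join(out)


def _delete(seq: str, positions: list[int]) -> str:
    drop = set(positions)
    return "".join(a for i, a in enumerate(seq, start=1) if i not in drop)


def _make_paralogs(rng: random.Random, benign_residue: int) -> tuple[dict[str, str], dict]:
    """Six synthetic actins anchored on a random ACTA1-like sequence.

    ACTC1 differs at exactly 4 positions (one of them the planted benign
    residue, whose substituted residue the benign ACTA1 variant will
    reuse); the smooth-muscle isoforms differ more; the cytoplasmic
    isoforms are two residues shorter, mirroring the family's real
    length structure.  All pairwise identities stay >= 93% because at
    most 26 of 377 positions are touched per isoform.
    """
    acta1 = _random_protein(rng, 377)
    plan = {
        "ACTC1": (4, []),
        "ACTA2": (18, []),
        "ACTG2": (20, [3]),
        "ACTB": (22, [2, 3]),
        "ACTG1": (22, [2, 3]),
    }
    # substitutions cluster at a shared pool of variable positions, as in
    # the real family; any two isoforms then differ at <= 26 positions,
    # keeping every pairwise identity above 93%
    variable_pool = [benign_residue] + rng.sample(
        [p for p in range(6, 378)], 25
    )
    sequences = {"ACTA1": acta1}
    diff_positions: dict[str, list[int]] = {}
    for name, (n_subs, deletions) in plan.items():
        pool = [p for p in variable_pool if p not in deletions]
        if name == "ACTC1":
            picks = [benign_residue] + rng.sample(
                [p for p in pool if p != benign_residue], n_subs - 1
            )
        else:
            picks = rng.sample(pool, n_subs)
        picks = sorted(picks)
        mutated = _substitute(rng, acta1, picks)
        sequences[name] = _delete(mutated, deletions)
        diff_positions[name] = picks
    truth = {
        "diff_positions": diff_positions,
        "deletions": {"ACTG2": [3], "ACTB": [2, 3], "ACTG1": [2, 3]},
        "actc1_benign_alt": sequences["ACTC1"][benign_residue - 1],
    }
    return sequences, truth


def _map_to_isoform(residue: int, isoform: str) -> int | None:
    """Project an ACTA1 residue onto a paralog given the planted deletions."""
    deletions = {"ACTG2": [3], "ACTB": [2, 3], "ACTG1": [2, 3]}.get(isoform, [])
    if residue in deletions:
        return None
    return residue - sum(1 for d in deletions if d < residue)


# ------------------------------------------------------------------ variants


def _codon_span(residue: int) -> tuple[int, int]:
    return (3 * residue - 2, 3 * residue)


def _aa3(one: str) -> str:
    return _AA3[one]


def _phenotype(rng: random.Random) -> str:
    x = rng.random()
    acc = 0.0
    for name, w in _PHENOTYPES:
        acc += w
        if x < acc:
            return name
    return "other congenital myopathy"


def generate(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write the full synthetic bundle into *out_dir*.

    Returns the paths of kb.tsv, annot.tsv, popn.tsv, actins.fasta,
    paralog_reports.tsv and truth.json.  Byte-identical for a fixed
    spec (the seed is part of the spec).
    """
    spec.validate()
    rng = random.Random(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    benign_residue = 5
    sequences, seq_truth = _make_paralogs(rng, benign_residue)
    acta1 = sequences["ACTA1"]

    kb_rows: list[dict] = []
    annot_rows: list[dict] = []
    popn_rows: list[dict] = []
    truth_variants: dict[str, dict] = {}
    counts: dict[str, int] = {}

    def add_variant(
        cdna: str,
        protein: str,
        consequence: str,
        classification: str,
        inheritance: str,
        de_novo: str,
        clear_cut: bool,
        residue: int | None = None,
        cadd: float | None = None,
        spliceai: float | None = None,
        am: str | None = None,
        popn: tuple[int, int, float | None] | None = None,  # (ac, hom, oldest_age)
        phenotype: str | None = None,
    ) -> None:
        sources = ["HGMD", "LOVD", "ClinVar"]
        source = rng.choice(sources)
        n_sources = 2 if rng.random() < spec.multi_source_fraction else 1
        row = {
            "isoform": "ACTA1",
            "cdna_change": cdna,
            "protein_change": protein,
            "consequence": consequence,
            "inheritance": inheritance,
            "de_novo": de_novo,
            "allele_balance": "",
            "phenotypes": phenotype or "",
            "source": source,
            "classification": classification,
            "n_cases": str(rng.randint(1, 6)),
            "de_novo_count": "1" if de_novo == "confirmed" else "0",
        }
        kb_rows.append(row)
        if n_sources == 2:
            second = dict(row)
            second["source"] = rng.choice([s for s in sources if s != source])
            kb_rows.append(second)
        annot_rows.append(
            {
                "isoform": "ACTA1",
                "cdna_change": cdna,
                "protein_change": protein,
                "cadd_phred": f"{cadd:.2f}" if cadd is not None else "",
                "spliceai_max_delta": f"{spliceai:.2f}" if spliceai is not None else "",
                "alphamissense_class": am or "",
            }
        )
        if popn is not None:
            ac, hom, age = popn
            popn_rows.append(
                {
                    "isoform": "ACTA1",
                    "cdna_change": cdna,
                    "protein_change": protein,
                    "ac_v2": str(ac // 2),
                    "ac_v3": str(ac - ac // 2),
                    "hom_count": str(hom),
                    "oldest_age": f"{age:.0f}" if age is not None else "",
                }
            )
        truth_variants[cdna] = {
            "classification": classification,
            "inheritance": inheritance,
            "consequence": consequence,
            "clear_cut": clear_cut,
            "residue": residue,
        }
        counts[consequence] = counts.get(consequence, 0) + 1

    # ---- P/LP missense: 154 residues, 340 distinct cDNA changes
    residue_pool = [r for r in range(6, 378)]
    plp_residues = sorted(rng.sample(residue_pool, spec.n_plp_missense_residues))
    extra = rng.choices(plp_residues, k=spec.n_plp_missense - len(plp_residues))
    variant_residues = sorted(plp_residues + extra)
    used_cdna: set[str] = set()
    for r in variant_residues:
        start, _ = _codon_span(r)
        ref_aa = acta1[r - 1]
        for _ in range(40):
            offset = rng.randint(0, 2)
            ref_nt, alt_nt = rng.sample("ACGT", 2)
            cdna = f"c.{start + offset}{ref_nt}>{alt_nt}"
            if cdna not in used_cdna:
                used_cdna.add(cdna)
                break
        else:  # pragma: no cover - 40 draws over 9 slots cannot all collide
            raise FixtureError(f"could not find a free codon change at residue {r}")
        alt_aa = rng.choice([a for a in _AA20 if a != ref_aa])
        de_novo = "confirmed" if rng.random() < spec.de_novo_fraction else "inherited"
        add_variant(
            cdna,
            f"p.{_aa3(ref_aa)}{r}{_aa3(alt_aa)}",
            "missense",
            rng.choice(["P", "P", "P", "LP"]),
            "dominant",
            de_novo,
            clear_cut=True,
            residue=r,
            cadd=rng.uniform(20.5, 35.0),
            spliceai=rng.uniform(0.0, 0.1),
            am="likely_pathogenic",
            phenotype=_phenotype(rng),
        )

    # ---- recessive (and NMD-escape dominant) frameshifts
    fs_positions = rng.sample(range(10, 800), spec.n_frameshift - spec.n_nmd_escape_frameshift)
    for p in sorted(fs_positions):
        r = (p + 2) // 3
        add_variant(
            f"c.{p}del",
            f"p.{_aa3(acta1[r - 1])}{r}fs",
            "frameshift",
            "P",
            "recessive",
            "unknown",
            clear_cut=True,
            residue=r,
            popn=(rng.randint(1, 10), 0, None)
            if rng.random() < spec.recessive_population_fraction
            else None,
        )
    for _ in range(spec.n_nmd_escape_frameshift):
        p = rng.randint(941, 1120)
        r = (p + 2) // 3
        add_variant(
            f"c.{p}del",
            f"p.{_aa3(acta1[r - 1])}{r}fs",
            "frameshift",
            "P",
            "dominant",
            "confirmed",
            clear_cut=True,
            residue=r,
        )

    # ---- recessive nonsense
    for r in sorted(rng.sample(range(4, 268), spec.n_nonsense)):
        start, _ = _codon_span(r)
        ref_nt, alt_nt = rng.sample("ACGT", 2)
        add_variant(
            f"c.{start}{ref_nt}>{alt_nt}",
            f"p.{_aa3(acta1[r - 1])}{r}Ter",
            "nonsense",
            "P",
            "recessive",
            "unknown",
            clear_cut=True,
            residue=r,
            popn=(rng.randint(1, 4), 0, None)
            if rng.random() < spec.recessive_population_fraction
            else None,
        )

    # ---- canonical splice variants (recessive)
    splice_slots = [(s, off, "splice_acceptor") for s in _EXON_STARTS for off in (-1, -2)]
    splice_slots += [(e, off, "splice_donor") for e in _EXON_ENDS for off in (1, 2)]
    for anchor, off, kind in sorted(rng.sample(splice_slots, spec.n_splice)):
        ref_nt, alt_nt = rng.sample("ACGT", 2)
        add_variant(
            f"c.{anchor}{off:+d}{ref_nt}>{alt_nt}",
            "",
            kind,
            "P",
            "recessive",
            "unknown",
            clear_cut=True,
            spliceai=rng.uniform(0.2, 1.0),
        )

    # ---- in-frame deletions (dominant)
    for r in sorted(rng.sample([x for x in residue_pool if x not in plp_residues], spec.n_inframe)):
        start, end = _codon_span(r)
        de_novo = "confirmed" if rng.random() < spec.de_novo_fraction else "inherited"
        add_variant(
            f"c.{start}_{end}del",
            f"p.{_aa3(acta1[r - 1])}{r}del",
            "inframe_del",
            "LP",
            "dominant",
            de_novo,
            clear_cut=(de_novo == "confirmed"),
            residue=r,
            phenotype=_phenotype(rng),
        )

    # ---- stop-loss SNVs (dominant; all append the same C-terminal extension)
    stop_changes = [("c.1132T>C", "Gln"), ("c.1133A>G", "Trp"), ("c.1134G>T", "Tyr")]
    for cdna, alt in stop_changes[: spec.n_stop_loss]:
        add_variant(
            cdna,
            f"p.Ter378{alt}extTer47",
            "stop_loss",
            "P",
            "dominant",
            "confirmed",
            clear_cut=True,
        )

    # ---- start-loss (recessive null)
    start_changes = ["c.2T>C", "c.1A>G"]
    for cdna in start_changes[: spec.n_start_loss]:
        add_variant(cdna, "p.Met1?", "start_loss", "P", "recessive", "unknown", clear_cut=True)

    # ---- the single benign missense, at a poorly conserved residue whose
    #      substituted residue is the wild-type ACTC1 one
    if spec.n_benign_missense:
        ref_aa = acta1[benign_residue - 1]
        alt_aa = seq_truth["actc1_benign_alt"]
        if alt_aa == ref_aa:  # conservative plan guarantees a difference
            alt_aa = "E" if ref_aa != "E" else "D"
        add_variant(
            f"c.{3 * benign_residue}C>G",
            f"p.{_aa3(ref_aa)}{benign_residue}{_aa3(alt_aa)}",
            "missense",
            "B",
            "unknown",
            "unknown",
            clear_cut=True,
            residue=benign_residue,
            cadd=rng.uniform(5.0, 15.0),
            am="likely_benign",
            popn=(rng.randint(40, 400), 0, rng.uniform(55, 80)),
        )
        for _ in range(spec.n_benign_missense - 1):
            r = rng.choice([x for x in range(6, 378) if x not in plp_residues])
            ref_aa = acta1[r - 1]
            alt_aa = rng.choice([a for a in _AA20 if a != ref_aa])
            start, _ = _codon_span(r)
            add_variant(
                f"c.{start}{rng.choice('AC')}>{rng.choice('GT')}",
                f"p.{_aa3(ref_aa)}{r}{_aa3(alt_aa)}",
                "missense",
                "B",
                "unknown",
                "unknown",
                clear_cut=True,
                residue=r,
                cadd=rng.uniform(5.0, 15.0),
                am="likely_benign",
                popn=(rng.randint(40, 400), 0, rng.uniform(55, 80)),
            )

    # ---- benign synonymous and intronic variants
    n_syn = spec.n_benign_other * 2 // 3
    syn_residues = rng.sample([x for x in range(6, 378)], min(n_syn, 370))
    high_spliceai_left = spec.n_benign_high_spliceai
    for r in sorted(syn_residues):
        _, last = _codon_span(r)
        ref_nt, alt_nt = rng.sample("ACGT", 2)
        cdna = f"c.{last}{ref_nt}>{alt_nt}"
        if cdna in used_cdna:
            continue
        used_cdna.add(cdna)
        spliceai = rng.uniform(0.0, 0.1)
        if high_spliceai_left > 0:
            spliceai = rng.uniform(0.2, 0.99)
            high_spliceai_left -= 1
        add_variant(
            cdna,
            f"p.{_aa3(acta1[r - 1])}{r}=",
            "synonymous",
            rng.choice(["B", "LB"]),
            "unknown",
            "unknown",
            clear_cut=True,
            cadd=rng.uniform(0.5, 12.0),
            spliceai=spliceai,
            popn=(rng.randint(20, 500), 0, rng.uniform(55, 80)),
        )
    n_intronic = spec.n_benign_other - n_syn
    intronic_slots: list[str] = []
    for anchor in _EXON_STARTS:
        intronic_slots += [f"c.{anchor}-{off}" for off in range(3, 30)]
    for anchor in _EXON_ENDS:
        intronic_slots += [f"c.{anchor}+{off}" for off in range(3, 30)]
    for slot in sorted(rng.sample(intronic_slots, n_intronic)):
        ref_nt, alt_nt = rng.sample("ACGT", 2)
        add_variant(
            f"{slot}{ref_nt}>{alt_nt}",
            "",
            "intronic",
            rng.choice(["B", "LB"]),
            "unknown",
            "unknown",
            clear_cut=True,
            cadd=rng.uniform(0.5, 10.0),
            spliceai=rng.uniform(0.0, 0.1),
            popn=(rng.randint(20, 500), 0, rng.uniform(55, 80)),
        )

    # ---- planted VUS: missense with ambiguous in-silico support, no de novo
    vus_pool = [x for x in range(6, 378) if x not in plp_residues and x != benign_residue]
    for r in sorted(rng.sample(vus_pool, spec.n_vus_missense)):
        start, _ = _codon_span(r)
        ref_nt, alt_nt = rng.sample("ACGT", 2)
        ref_aa = acta1[r - 1]
        alt_aa = rng.choice([a for a in _AA20 if a != ref_aa])
        add_variant(
            f"c.{start + 1}{ref_nt}>{alt_nt}",
            f"p.{_aa3(ref_aa)}{r}{_aa3(alt_aa)}",
            "missense",
            "VUS",
            "unknown",
            "unknown",
            clear_cut=False,
            residue=r,
            cadd=rng.uniform(18.0, 24.0),
            am="ambiguous",
        )

    # ---- population-only missense residues (overlap planted exactly)
    overlap = sorted(rng.sample(plp_residues, spec.n_popn_overlap_residues))
    nonpath_pool = [
        x for x in range(6, 378) if x not in plp_residues and x != benign_residue
    ]
    non_overlap = sorted(
        rng.sample(nonpath_pool, spec.n_popn_missense_residues - spec.n_popn_overlap_residues)
    )
    popn_missense_residues = sorted(overlap + non_overlap)
    for r in popn_missense_residues:
        start, _ = _codon_span(r)
        ref_aa = acta1[r - 1]
        alt_aa = rng.choice([a for a in _AA20 if a != ref_aa])
        for _ in range(40):
            offset = rng.randint(0, 2)
            ref_nt, alt_nt = rng.sample("ACGT", 2)
            cdna = f"c.{start + offset}{ref_nt}>{alt_nt}"
            if cdna not in used_cdna:
                used_cdna.add(cdna)
                break
        popn_rows.append(
            {
                "isoform": "ACTA1",
                "cdna_change": cdna,
                "protein_change": f"p.{_aa3(ref_aa)}{r}{_aa3(alt_aa)}",
                "ac_v2": str(rng.randint(0, 3)),
                "ac_v3": str(rng.randint(1, 3)),
                "hom_count": "0",
                "oldest_age": "",
            }
        )

    # ---- paralog report snapshot with a planted ACTA1-projected union
    union_pool = [
        x for x in range(6, 378) if x not in plp_residues and x != benign_residue
    ]
    union_extra = sorted(rng.sample(union_pool, spec.n_union_residues - len(plp_residues)))
    union = sorted(plp_residues + union_extra)
    quotas = dict(spec.paralog_residue_counts)
    assignment: dict[str, list[int]] = {iso: [] for iso in quotas}
    assignment["ACTA1"] = list(plp_residues)
    quotas["ACTA1"] = 0
    # every non-ACTA1 union residue must be covered by at least one paralog
    for r in union_extra:
        candidates = [
            iso
            for iso, quota in quotas.items()
            if iso != "ACTA1"
            and len(assignment[iso]) < quota
            and _map_to_isoform(r, iso) is not None
        ]
        if not candidates:
            raise FixtureError("paralog quotas too small to cover the requested union")
        iso = rng.choice(candidates)
        assignment[iso].append(r)
    # fill remaining quotas from the union (duplicates across isoforms)
    for iso, quota in quotas.items():
        if iso == "ACTA1":
            continue
        pool = [r for r in union if r not in assignment[iso] and _map_to_isoform(r, iso) is not None]
        need = quota - len(assignment[iso])
        if need > 0:
            assignment[iso].extend(rng.sample(pool, need))
        assignment[iso].sort()

    report_rows = []
    for iso in sorted(assignment):
        seq = sequences[iso]
        for r in assignment[iso]:
            local = r if iso == "ACTA1" else _map_to_isoform(r, iso)
            ref_aa = seq[local - 1]
            alt_aa = rng.choice([a for a in _AA20 if a != ref_aa])
            report_rows.append(
                {
                    "isoform": iso,
                    "protein_change": f"p.{_aa3(ref_aa)}{local}{_aa3(alt_aa)}",
                    "classification": rng.choice(["P", "P", "LP"]),
                    "source": rng.choice(["HGMD", "LOVD", "ClinVar"]),
                }
            )

    # --------------------------------------------------------------- write
    paths = {
        "kb": out_dir / "kb.tsv",
        "annot": out_dir / "annot.tsv",
        "popn": out_dir / "popn.tsv",
        "fasta": out_dir / "actins.fasta",
        "paralog_reports": out_dir / "paralog_reports.tsv",
        "truth": out_dir / "truth.json",
    }
    _write_tsv(paths["kb"], kb_rows)
    _write_tsv(paths["annot"], annot_rows)
    _write_tsv(paths["popn"], popn_rows)
    _write_tsv(paths["paralog_reports"], report_rows)
    with open(paths["fasta"], "w") as fh:
        for name in ["ACTA1", "ACTC1", "ACTA2", "ACTG2", "ACTB", "ACTG1"]:
            fh.write(f">{name} synthetic\n{sequences[name]}\n")
    truth = {
        "seed": spec.seed,
        "spec": dataclasses.asdict(spec),
        "variants": truth_variants,
        "plp_missense_residues": plp_residues,
        "benign_missense_residue": benign_residue,
        "popn_missense_residues": popn_missense_residues,
        "popn_overlap_residues": overlap,
        "union_residues": union,
        "paralog_assignment": {k: v for k, v in sorted(assignment.items())},
        "sequences": seq_truth,
        "counts": dict(sorted(counts.items())),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def _write_tsv(path: Path, rows: list[dict]) -> None:
    if not rows:
        path.write_text("")
        return
    cols = list(rows[0])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in cols) + "\n")


# ------------------------------------------------------------- toy paralogs


def toy_paralogs(
    n_isoforms: int, length: int, n_diffs: int, n_gap_cols: int, seed: int = 0
) -> tuple[dict[str, str], dict]:
    """Small paralog sets with an exactly known mismatch/gap structure.

    Every isoform after the first carries exactly *n_diffs* substitutions
    and *n_gap_cols* single-residue deletions relative to the first; the
    returned truth map lists the positions touched per isoform.
    """
    if n_diffs + n_gap_cols >= length:
        raise FixtureError("n_diffs + n_gap_cols must be < length")
    if n_isoforms < 1:
        raise FixtureError("need at least one isoform")
    rng = random.Random(seed)
    base = "".join(rng.choice(_AA20) for _ in range(length))
    sequences = {"ISO1": base}
    truth: dict[str, dict] = {"ISO1": {"diff_positions": [], "deleted_positions": []}}
    for i in range(2, n_isoforms + 1):
        picks = rng.sample(range(1, length + 1), n_diffs + n_gap_cols)
        diffs = sorted(picks[:n_diffs])
        gaps = sorted(picks[n_diffs:])
        seq = _substitute(rng, base, diffs)
        seq = _delete(seq, gaps)
        name = f"ISO{i}"
        sequences[name] = seq
        truth[name] = {"diff_positions": diffs, "deleted_positions": gaps}
    return sequences, truth
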