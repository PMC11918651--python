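import pytest

from actinterp.evidence import (
    EvidenceItem,
    FamilyEvidence,
    RuleConfig,
    compute_hotspots,
    evaluate,
    region_qualifies,
)
from actinterp.knowledgebase import (
    AnnotationBundle,
    Knowledgebase,
    PopulationRecord,
    PriorReport,
    VariantRecord,
)
from actinterp.nomenclature import parse_cdna_change, parse_protein_change
from actinterp.paralog_map import ColumnEvidence, TIERS


def make_variant(protein=None, cdna=None, consequence="missense", **kw):
    return VariantRecord(
        isoform="ACTA1",
        protein_change=parse_protein_change(protein) if protein else None,
        cdna_change=parse_cdna_change(cdna) if cdna else None,
        consequence=consequence,
        **kw,
    )


def kb_with(*entries):
    """entries: (protein_change, classification) or records."""
    kb = Knowledgebase()
    for entry in entries:
        if isinstance(entry, VariantRecord):
            kb.add_record(entry)
            continue
        change, classification = entry
        pc = parse_protein_change(change)
        kb.add_record(
            VariantRecord(
                isoform="ACTA1",
                protein_change=pc,
                consequence=pc.kind,
                reports=[
                    PriorReport(
                        source="HGMD",
                        classification=classification,
                        isoform="ACTA1",
                        protein_change=pc,
                    )
                ],
            )
        )
    return kb


def column(conservation="variable", same_change=(), same_residue=(), distinct=0, benign=False):
    ev = ColumnEvidence(
        isoform="ACTA1",
        hgvs_residue=258,
        column=257,
        conservation=conservation,
        same_change={t: [] for t in TIERS},
        same_residue={t: [] for t in TIERS},
    )
    for tier in same_change:
        ev.same_change[tier].append(
            PriorReport(source="HGMD", classification="P", isoform="ACTC1")
        )
    for tier in same_residue:
        ev.same_residue[tier].append(
            PriorReport(source="HGMD", classification="P", isoform="ACTC1")
        )
    ev.distinct_plp_changes = {("Arg", chr(65 + i), "") for i in range(distinct)}
    ev.benign_at_column = benign
    return ev


class TestHotspots:
    def test_benign_delimiter_splits_regions(self):
        kb = kb_with(("p.Asp5Glu", "B"), ("p.Gly10Arg", "P"), ("p.Gly12Asp", "P"))
        regions = compute_hotspots(kb)
        assert [(r.start, r.end, r.qualifies) for r in regions] == [
            (1, 4, False),
            (6, 377, True),
        ]

    def test_no_pathogenic_variants_no_qualifying_regions(self):
        kb = kb_with(("p.Asp5Glu", "B"), ("p.Lys50Glu", "B"))
        assert not any(r.qualifies for r in compute_hotspots(kb))

    def test_mixed_residue_region_qualifies_via_count_path(self):
        # residue 50 carries both a pathogenic and (another variant's)
        # benign missense, so it does not delimit; the enclosing region
        # holds a benign variant yet qualifies with three pathogenic ones
        mixed_path = make_variant("p.Lys50Glu", cdna="c.148A>G")
        mixed_path.reports = [
            PriorReport(source="HGMD", classification="P", isoform="ACTA1",
                        protein_change=mixed_path.protein_change)
        ]
        mixed_benign = make_variant("p.Lys50Arg", cdna="c.149A>G")
        mixed_benign.reports = [
            PriorReport(source="LOVD", classification="LB", isoform="ACTA1",
                        protein_change=mixed_benign.protein_change)
        ]
        kb = kb_with(mixed_path, mixed_benign, ("p.Gly60Arg", "P"), ("p.Gly70Asp", "P"))
        [region] = compute_hotspots(kb)
        assert (region.start, region.end) == (1, 377)
        assert region.benign_count == 1 and region.pathogenic_count == 3
        assert region.qualifies

    @pytest.mark.parametrize(
        "path,benign,expected",
        [(1, 0, True), (0, 0, False), (3, 1, True), (2, 1, False), (3, 0, True)],
    )
    def test_dual_criterion(self, path, benign, expected):
        assert region_qualifies(path, benign) is expected


class TestEvaluateScenarios:
    def test_de_novo_missense_full_pattern(self):
        kb = kb_with(("p.Arg258Leu", "P"))
        kb.population = {}
        variant = make_variant("p.Arg258His", cdna="c.773G>A", de_novo="confirmed")
        annotations = AnnotationBundle(cadd_phred=29.0, alphamissense_class="likely_pathogenic")
        result = evaluate(variant, annotations=annotations, kb=kb)
        assert result.codes == {"PS2", "PM2", "PP2", "PP3", "PM5"}

    def test_benign_missense_pattern_and_no_pm1(self):
        kb = kb_with(("p.Asp5Glu", "B"), ("p.Gly10Arg", "P"))
        kb.population[("ACTA1", "c.15C>G")] = PopulationRecord(
            key=("ACTA1", "c.15C>G"), ac_v2=100, ac_v3=100, oldest_age=70, residue=5
        )
        variant = make_variant("p.Asp5Glu", cdna="c.15C>G")
        annotations = AnnotationBundle(cadd_phred=9.0, alphamissense_class="likely_benign")
        hotspots = compute_hotspots(kb)
        result = evaluate(variant, annotations=annotations, kb=kb, hotspots=hotspots)
        assert result.codes == {"PP2", "BS2", "BS1"}
        assert "benign_leaning_in_silico" in result.flags

    def test_synonymous_spliceai_thresholds(self):
        variant = make_variant("p.Lys70=", cdna="c.210G>A", consequence="synonymous")
        low = evaluate(variant, annotations=AnnotationBundle(spliceai_max_delta=0.05))
        assert not low.items
        mid = evaluate(variant, annotations=AnnotationBundle(spliceai_max_delta=0.3))
        assert not mid.items and "possible_splice_altering" in mid.flags
        high = evaluate(variant, annotations=AnnotationBundle(spliceai_max_delta=0.99))
        assert high.codes == {"PP3"}

    def test_stop_loss_snv_gets_pvs1_but_indel_does_not(self):
        snv = make_variant("p.Ter378GlnextTer47", cdna="c.1132T>C", consequence="stop_loss")
        assert "PVS1" in evaluate(snv).codes
        indel = make_variant(cdna="c.1130_1133del", consequence="stop_loss")
        result = evaluate(indel)
        assert "PVS1" not in result.codes
        assert "stop_loss_indel_requires_review" in result.flags

    def test_null_variant_tracks(self):
        fs = make_variant("p.Asp181ThrfsTer11", cdna="c.541del", consequence="frameshift")
        dominant = evaluate(fs, track="dominant")
        recessive = evaluate(fs, track="recessive")
        assert "PVS1" not in dominant.codes
        assert "null_variant_recessive_candidate" in dominant.flags
        assert "PVS1" in recessive.codes
        assert "check_second_allele" in recessive.flags

    def test_nmd_escaping_frameshift_is_dominant_candidate(self):
        fs = make_variant("p.Gly344fs", cdna="c.1031del", consequence="frameshift")
        assert "PVS1" in evaluate(fs, track="dominant").codes

    def test_recessive_pm2_requires_no_homozygotes(self):
        kb = Knowledgebase()
        kb.population[("ACTA1", "c.541del")] = PopulationRecord(
            key=("ACTA1", "c.541del"), ac_v2=10, hom_count=0
        )
        fs = make_variant("p.Asp181ThrfsTer11", cdna="c.541del", consequence="frameshift")
        recessive = evaluate(fs, kb=kb, track="recessive")
        assert "PM2" in recessive.codes
        dominant = evaluate(fs, kb=kb, track="dominant")
        assert "PM2" not in dominant.codes
        kb.population[("ACTA1", "c.541del")].hom_count = 2
        assert "PM2" not in evaluate(fs, kb=kb, track="recessive").codes

    def test_phenotype_specificity_pp4(self):
        nem = make_variant("p.Arg258His", phenotypes=("nemaline myopathy",))
        assert "PP4" in evaluate(nem).codes
        other = make_variant("p.Arg258His", phenotypes=("distal myopathy",))
        assert "PP4" not in evaluate(other).codes

    def test_pp1_meioses_tiers(self):
        variant = make_variant("p.Arg258His")
        for meioses, strength in ((3, "supporting"), (5, "moderate"), (8, "strong")):
            result = evaluate(variant, family=FamilyEvidence(de_novo="none", meioses=meioses))
            [pp1] = [it for it in result.items if it.code == "PP1"]
            assert pp1.strength == strength
        none = evaluate(variant, family=FamilyEvidence(de_novo="none", meioses=2))
        assert "PP1" not in none.codes

    def test_assumed_de_novo_pm6(self):
        result = evaluate(make_variant("p.Arg258His"), family=FamilyEvidence(de_novo="assumed"))
        assert "PM6" in result.codes and "PS2" not in result.codes


class TestParalogRules:
    def test_actc1_same_change_is_firm_strong_ps1(self):
        result = evaluate(make_variant("p.Arg258His"), paralog_evidence=column(same_change=("cardiac",)))
        [ps1] = [it for it in result.items if it.code == "PS1"]
        assert ps1.strength == "strong" and ps1.confidence == "firm" and ps1.rule_id == "R14"

    def test_tier_weighting_downgrades_strength(self):
        smooth = evaluate(make_variant("p.Arg258His"), paralog_evidence=column(same_change=("smooth",)))
        [ps1] = [it for it in smooth.items if it.code == "PS1"]
        assert ps1.strength == "moderate" and ps1.confidence == "provisional"
        cyto = evaluate(make_variant("p.Arg258His"), paralog_evidence=column(same_change=("cytoplasmic",)))
        [ps1] = [it for it in cyto.items if it.code == "PS1"]
        assert ps1.strength == "supporting" and ps1.confidence == "provisional"

    def test_conserved_column_provisional_pm1(self):
        result = evaluate(make_variant("p.Arg258His"), paralog_evidence=column(conservation="identical"))
        [pm1] = [it for it in result.items if it.code == "PM1"]
        assert pm1.confidence == "provisional" and pm1.rule_id == "R12"

    def test_recurrent_conserved_column_firm_pm1_wins(self):
        ev = column(conservation="identical", distinct=2)
        result = evaluate(make_variant("p.Arg258His"), paralog_evidence=ev)
        pm1 = [it for it in result.items if it.code == "PM1"]
        assert len(pm1) == 1
        assert pm1[0].rule_id == "R17" and pm1[0].confidence == "firm"

    def test_benign_at_column_blocks_r17(self):
        ev = column(conservation="identical", distinct=2, benign=True)
        result = evaluate(make_variant("p.Arg258His"), paralog_evidence=ev)
        [pm1] = [it for it in result.items if it.code == "PM1"]
        assert pm1.rule_id == "R12"

    def test_at_most_one_pm1_with_hotspot(self):
        kb = kb_with(("p.Gly10Arg", "P"))
        hotspots = compute_hotspots(kb)
        ev = column(conservation="identical")
        result = evaluate(
            make_variant("p.Arg258His"), kb=kb, paralog_evidence=ev, hotspots=hotspots
        )
        pm1 = [it for it in result.items if it.code == "PM1"]
        assert len(pm1) == 1
        assert pm1[0].rule_id == "SW-PM1" and pm1[0].strength == "moderate"

    def test_paralog_pm5_not_doubled_with_acta1_pm5(self):
        kb = kb_with(("p.Arg258Leu", "P"))
        ev = column(same_residue=("cardiac",))
        result = evaluate(make_variant("p.Arg258His"), kb=kb, paralog_evidence=ev)
        pm5 = [it for it in result.items if it.code == "PM5"]
        assert len(pm5) == 1 and pm5[0].rule_id == "R9"


class TestRuleIndependence:
    def test_removing_an_annotation_only_removes_its_rules(self):
        kb = kb_with(("p.Arg258Leu", "P"))
        variant = make_variant("p.Arg258His", cdna="c.773G>A", de_novo="confirmed")
        full = AnnotationBundle(
            cadd_phred=29.0, spliceai_max_delta=0.9, alphamissense_class="likely_pathogenic"
        )
        base = evaluate(variant, annotations=full, kb=kb)
        no_splice = evaluate(
            variant,
            annotations=AnnotationBundle(cadd_phred=29.0, alphamissense_class="likely_pathogenic"),
            kb=kb,
        )
        removed = {it.rule_id for it in base.items} - {it.rule_id for it in no_splice.items}
        assert removed == {"R5"}
        no_kb = evaluate(variant, annotations=full)
        removed = {it.rule_id for it in base.items} - {it.rule_id for it in no_kb.items}
        assert removed <= {"R9", "R10"}

    def test_adding_pathogenic_prior_is_monotone(self):
        variant = make_variant("p.Arg258His", cdna="c.773G>A")
        before = evaluate(variant, kb=Knowledgebase())
        kb = kb_with(("p.Arg258His", "P"), ("p.Arg258Leu", "P"))
        after = evaluate(variant, kb=kb)
        pathogenic_before = {it.code for it in before.items if not it.benign_side}
        pathogenic_after = {it.code for it in after.items if not it.benign_side}
        assert pathogenic_before <= pathogenic_after
        assert not {it.code for it in after.items if it.benign_side}


class TestConfig:
    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="PX9"):
            EvidenceItem("PX9", "strong", "R1")

    def test_config_round_trip_from_yaml(self, tmp_path):
        path = tmp_path / "rules.yaml"
        path.write_text("cadd_pathogenic: 25\npp4_phenotypes:\n  - nemaline myopathy\n")
        cfg = RuleConfig.from_yaml(path)
        assert cfg.cadd_pathogenic == 25
        assert cfg.pp4_phenotypes == ("nemaline myopathy",)
        variant = make_variant("p.Arg258His")
        ann = AnnotationBundle(cadd_phred=22.0, alphamissense_class="likely_pathogenic")
        assert "PP3" not in evaluate(variant, annotations=ann, config=cfg).codes

    def test_unknown_track_rejected(self):
        with pytest.raises(ValueError, match="track"):
            evaluate(make_variant("p.Arg258His"), track="codominant")
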