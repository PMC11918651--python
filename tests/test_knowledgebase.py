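import textwrap

import pytest

from actinterp.knowledgebase import (
    Knowledgebase,
    PopulationRecord,
    PriorReport,
    VariantRecord,
)
from actinterp.nomenclature import parse_cdna_change, parse_protein_change


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(textwrap.dedent(text).lstrip())
    return path


KB_HEADER = (
    "isoform\tcdna_change\tprotein_change\tconsequence\tinheritance\tde_novo\t"
    "allele_balance\tphenotypes\tsource\tclassification\tn_cases\tde_novo_count"
)


@pytest.fixture
def ten_row_kb(tmp_path):
    rows = [
        "ACTA1\tc.15C>G\tp.Asp5Glu\tmissense\tunknown\tunknown\t\t\tClinVar\tB\t1\t0",
        "ACTA1\tc.773G>A\tp.Arg258His\tmissense\tdominant\tconfirmed\t\tnemaline myopathy\tHGMD\tP\t3\t2",
        "ACTA1\tc.773G>A\tp.Arg258His\tmissense\tdominant\tconfirmed\t\tnemaline myopathy\tLOVD\tP\t2\t1",
        "ACTA1\tc.772C>T\tp.Arg258Cys\tmissense\tdominant\tconfirmed\t\tnemaline myopathy\tHGMD\tLP\t1\t1",
        "ACTA1\tc.541delG\tp.Asp181ThrfsTer11\tframeshift\trecessive\tunknown\t\t\tHGMD\tP\t4\t0",
        "ACTA1\tc.617-5C>A\t\tsplice_region\tdominant\tunknown\t\t\tLOVD\tP\t1\t0",
        "ACTA1\tc.1132T>C\tp.Ter378GlnextTer47\tstop_loss\tdominant\tconfirmed\t\t\tHGMD\tP\t1\t1",
        "ACTA1\tc.210G>A\tp.Lys70=\tsynonymous\tunknown\tunknown\t\t\tLOVD\tLB\t1\t0",
        "ACTC1\t\tp.Arg258His\tmissense\tdominant\tunknown\t\t\tClinVar\tP\t1\t0",
        "ACTA1\tc.115C>G\tp.Arg39Gly\tmissense\tdominant\tunknown\t0.09\t\tliterature\tVUS\t1\t0",
    ]
    return _write(tmp_path, "kb.tsv", KB_HEADER + "\n" + "\n".join(rows) + "\n")


class TestLoading:
    def test_duplicate_rows_merge_into_one_record(self, ten_row_kb):
        kb = Knowledgebase().load_variants(ten_row_kb)
        assert not kb.errors
        assert len(kb.records) == 9
        merged = kb.records[("ACTA1", "c.773G>A")]
        assert len(merged.reports) == 2
        assert {r.source for r in merged.reports} == {"HGMD", "LOVD"}

    def test_legacy_protein_label_is_normalized(self, tmp_path):
        path = _write(
            tmp_path,
            "legacy.tsv",
            KB_HEADER + "\nACTA1\t\tR256H (legacy)\tmissense\tdominant\tunknown\t\t\tHGMD\tP\t1\t0\n",
        )
        kb = Knowledgebase().load_variants(path)
        [rec] = kb.records.values()
        assert str(rec.protein_change) == "p.Arg258His"

    def test_header_only_file_loads_empty(self, tmp_path):
        kb = Knowledgebase().load_variants(_write(tmp_path, "empty.tsv", KB_HEADER + "\n"))
        assert kb.records == {} and not kb.errors

    def test_malformed_row_collected_not_raised(self, tmp_path):
        path = _write(
            tmp_path,
            "bad.tsv",
            KB_HEADER
            + "\nACTA1\tc.??\tp.??\tmissense\tdominant\tunknown\t\t\tHGMD\tP\t1\t0\n"
            + "ACTA1\tc.15C>G\tp.Asp5Glu\tmissense\tunknown\tunknown\t\t\tClinVar\tB\t1\t0\n",
        )
        kb = Knowledgebase().load_variants(path)
        assert len(kb.records) == 1
        assert len(kb.errors) == 1 and "row 2" in kb.errors[0]

    def test_unknown_columns_warn_and_are_ignored(self, tmp_path):
        path = _write(
            tmp_path,
            "extra.tsv",
            KB_HEADER + "\tmystery\nACTA1\tc.15C>G\tp.Asp5Glu\tmissense\tunknown\tunknown\t\t\tClinVar\tB\t1\t0\tx\n",
        )
        with pytest.warns(UserWarning, match="mystery"):
            kb = Knowledgebase().load_variants(path)
        assert len(kb.records) == 1

    def test_exon_assignment_attached(self, ten_row_kb):
        kb = Knowledgebase().load_variants(ten_row_kb)
        assert kb.records[("ACTA1", "c.773G>A")].region == "Exon5"
        assert kb.records[("ACTA1", "c.617-5C>A")].region == "Intron4"

    def test_dedup_is_idempotent(self, ten_row_kb):
        kb = Knowledgebase().load_variants(ten_row_kb)
        kb.load_variants(ten_row_kb)  # same file again
        assert len(kb.records) == 9
        assert len(kb.records[("ACTA1", "c.773G>A")].reports) == 2


class TestQueries:
    def test_same_change_reports(self, ten_row_kb):
        kb = Knowledgebase().load_variants(ten_row_kb)
        reports = kb.same_change_reports("ACTA1", "p.Asp5Glu")
        assert len(reports) == 1 and reports[0].is_benign
        assert kb.same_change_reports("ACTA1", "p.Gly15Arg") == []
        assert len(kb.same_change_reports("ACTA1", "p.Arg258His")) == 2

    def test_same_residue_excludes_the_query_change(self, ten_row_kb):
        kb = Knowledgebase().load_variants(ten_row_kb)
        reports = kb.same_residue_reports("ACTA1", 258, "p.Arg258Leu")
        assert len(reports) == 3  # His (two sources) + Cys
        only = kb.same_residue_reports("ACTA1", 5, "p.Asp5Glu")
        assert only == []

    def test_three_distinct_changes_at_one_residue(self, tmp_path):
        rows = "\n".join(
            f"ACTA1\t\tp.Arg258{alt}\tmissense\tdominant\tunknown\t\t\tHGMD\tP\t1\t0"
            for alt in ("His", "Leu", "Gly")
        )
        kb = Knowledgebase().load_variants(_write(tmp_path, "r.tsv", KB_HEADER + "\n" + rows + "\n"))
        assert len(kb.same_residue_reports("ACTA1", 258, "p.Arg258Ser")) == 3


class TestPopulation:
    POPN = (
        "isoform\tcdna_change\tprotein_change\tac_v2\tac_v3\thom_count\toldest_age\n"
        "ACTA1\tc.541delG\tp.Asp181ThrfsTer11\t6\t4\t0\t\n"
        "ACTA1\tc.15C>G\tp.Asp5Glu\t120\t80\t1\t70\n"
    )

    def test_presence_states(self, tmp_path):
        kb = Knowledgebase().load_population(_write(tmp_path, "popn.tsv", self.POPN))
        assert kb.population_presence(("ACTA1", "c.541delG")) == ("present_het", None)
        assert kb.population_presence(("ACTA1", "c.15C>G")) == ("present_hom", 70)
        assert kb.population_presence(("ACTA1", "c.999G>A")) == ("absent", None)

    def test_homozygote_count_bounded_by_alleles(self, tmp_path):
        bad = (
            "isoform\tcdna_change\tprotein_change\tac_v2\tac_v3\thom_count\toldest_age\n"
            "ACTA1\tc.15C>G\t\t1\t1\t3\t\n"
        )
        kb = Knowledgebase().load_population(_write(tmp_path, "bad.tsv", bad))
        assert kb.errors and "homozygote" in kb.errors[0]


class TestRoundTrip:
    def test_json_round_trip_is_stable(self, ten_row_kb, tmp_path):
        kb = Knowledgebase().load_variants(ten_row_kb)
        popn = _write(tmp_path, "popn.tsv", TestPopulation.POPN)
        kb.load_population(popn)
        text = kb.to_json()
        kb2 = Knowledgebase.from_json(text)
        assert kb2.to_json() == text
        assert set(kb2.records) == set(kb.records)


class TestVcf:
    def test_minimal_vcf_ingestion(self, tmp_path):
        vcf = tmp_path / "v.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=1,length=249250621>\n'
            '##INFO=<ID=HGVSC,Number=1,Type=String,Description="cDNA change">\n'
            '##INFO=<ID=HGVSP,Number=1,Type=String,Description="protein change">\n'
            '##INFO=<ID=CONSEQ,Number=1,Type=String,Description="consequence">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "1\t229431245\t.\tC\tG\t.\t.\tHGVSC=c.15C>G;HGVSP=p.Asp5Glu;CONSEQ=missense\n"
        )
        kb = Knowledgebase().load_vcf(vcf)
        assert not kb.errors
        [rec] = kb.records.values()
        assert rec.key == ("ACTA1", "c.15C>G")
        assert rec.consequence == "missense"


class TestValidation:
    def test_inconsistent_consequence_flagged(self, tmp_path):
        path = _write(
            tmp_path,
            "v.tsv",
            KB_HEADER + "\nACTA1\tc.15C>G\t\tintronic\tunknown\tunknown\t\t\tHGMD\tB\t1\t0\n",
        )
        kb = Knowledgebase().load_variants(path)
        assert any("intronic" in w for w in kb.validate())

    def test_residue_outside_isoform_rejected(self):
        with pytest.raises(ValueError, match="ACTB"):
            VariantRecord(
                isoform="ACTB",
                protein_change=parse_protein_change("p.Arg376His"),
                consequence="missense",
            )

    def test_bundle_validates_cleanly(self, bundle):
        assert bundle["kb"].validate() == []
        assert bundle["kb"].errors == []
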