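"""Phenotype assignment, unit conversion, profile categories, diagnoses,
and cohort summaries."""

import pytest

import lipidpanel as lp
from lipidpanel.cnv_caller import CnvCall
from lipidpanel.errors import ProfileError
from lipidpanel.genetic_profile import (
    gene_allelic_states,
    profiles_from_counts,
    round_half_away,
)

from conftest import make_variant


class TestPhenotypeAssignment:
    @pytest.mark.parametrize(
        "lipids, expected",
        [
            (dict(triglyceride=12.0), "severe_HTG"),
            (dict(triglyceride=10.0), "severe_HTG"),  # inclusive
            (dict(ldl_chol=5.0, triglyceride=1.0), "unclassified"),  # strict >
            (dict(ldl_chol=5.01, triglyceride=1.0), "FH"),
            (dict(triglyceride=1.8), "HTG"),  # inclusive
            (dict(triglyceride=1.79), "unclassified"),
            (dict(ldl_chol=5.5, triglyceride=2.5), "familial_combined"),
            (dict(ldl_chol=6.0, triglyceride=11.0), "severe_HTG"),  # precedence
            (dict(lpa=36.0, ldl_chol=3.0), "high_Lpa"),
            (dict(lpa=35.9, ldl_chol=3.0), "unclassified"),
        ],
    )
    def test_threshold_boundaries_and_precedence(self, lipids, expected):
        assert lp.assign_phenotype(lp.LipidProfile(**lipids)) == expected

    def test_all_missing_profile_rejected(self):
        with pytest.raises(ProfileError, match="missing"):
            lp.assign_phenotype(lp.LipidProfile())

    def test_negative_lipid_rejected(self):
        with pytest.raises(ProfileError, match="negative"):
            lp.LipidProfile(ldl_chol=-1.0)


class TestUnitConversion:
    @pytest.mark.parametrize(
        "value, analyte, expected",
        [
            (1.0, "cholesterol", 38.67),
            (1.0, "triglyceride", 88.57),
            (0.0, "cholesterol", 0.0),
            (5.0, "cholesterol", 193.35),
        ],
    )
    def test_conversion_factors(self, value, analyte, expected):
        assert lp.convert_units(value, analyte) == pytest.approx(expected)

    def test_negative_value_rejected(self):
        with pytest.raises(ProfileError):
            lp.convert_units(-1.0, "cholesterol")


class TestCategory:
    def test_four_way_classification(self):
        snv = make_variant()
        cnv = CnvCall("S1", "LDLR", "Exons 2–6", "het_deletion")
        assert lp.classify_profile([snv], False) == "rare_only"
        assert lp.classify_profile([cnv], True) == "rare_plus_extreme"
        assert lp.classify_profile([], True) == "extreme_only"
        assert lp.classify_profile([], False) == "none"


class TestAllelicState:
    def test_snv_dose_accumulates(self):
        het1 = make_variant(position=10)
        het2 = make_variant(position=20)
        hom = make_variant(position=30, zygosity="homozygous")
        assert gene_allelic_states([het1]) == {"LDLR": "heterozygous"}
        assert gene_allelic_states([het1, het2]) == {"LDLR": "biallelic"}
        assert gene_allelic_states([hom]) == {"LDLR": "biallelic"}

    def test_cnv_doses(self):
        het_del = CnvCall("S1", "GPIHBP1", "Exons 3–4", "het_deletion")
        hom_del = CnvCall("S1", "GPIHBP1", "5'UTR – 3'UTR", "hom_deletion")
        assert gene_allelic_states([het_del]) == {"GPIHBP1": "heterozygous"}
        assert gene_allelic_states([hom_del]) == {"GPIHBP1": "biallelic"}

    def test_snv_plus_cnv_is_compound_heterozygous(self):
        snv = make_variant(gene="LDLR")
        cnv = CnvCall("S1", "LDLR", "Exons 2–6", "het_deletion")
        assert gene_allelic_states([snv, cnv]) == {"LDLR": "biallelic"}

    def test_multiple_cnv_calls_count_as_one_allele(self):
        # a split or tandem event must not fake biallelic state
        a = CnvCall("S1", "PCSK9", "5'UTR – Exon 10", "duplication")
        b = CnvCall("S1", "PCSK9", "Exon 12 – 3'UTR", "duplication")
        assert gene_allelic_states([a, b]) == {"PCSK9": "heterozygous"}


@pytest.fixture(scope="module")
def rules(panel):
    return lp.default_diagnosis_rules(panel)


class TestDiagnosisRules:
    def test_heterozygous_fh_gene_gives_hefh(self, rules):
        findings = [make_variant(gene="LDLR")]
        assert lp.apply_diagnosis_rules(findings, "FH", rules) == "HeFH"

    def test_biallelic_fh_gene_gives_hofh(self, rules):
        findings = [make_variant(gene="LDLR", zygosity="homozygous")]
        assert lp.apply_diagnosis_rules(findings, "FH", rules) == "HoFH"

    def test_biallelic_abcg5_reclassifies_to_sitosterolemia(self, rules):
        findings = [make_variant(gene="ABCG5", zygosity="homozygous")]
        assert lp.apply_diagnosis_rules(findings, "HoFH", rules) == "Sitosterolemia"

    def test_two_het_lpl_variants_give_chylomicronemia(self, rules):
        findings = [
            make_variant(gene="LPL", position=10),
            make_variant(gene="LPL", position=20),
        ]
        assert (
            lp.apply_diagnosis_rules(findings, "HTG", rules)
            == "Familial chylomicronemia syndrome"
        )

    def test_biallelic_apoc2_takes_specific_label(self, rules):
        findings = [make_variant(gene="APOC2", zygosity="homozygous")]
        assert lp.apply_diagnosis_rules(findings, "HTG", rules) == "APOC2 deficiency"

    def test_hom_deletion_cnv_counts_as_biallelic(self, rules):
        findings = [CnvCall("S1", "GPIHBP1", "5'UTR – 3'UTR", "hom_deletion")]
        assert (
            lp.apply_diagnosis_rules(findings, "HTG", rules)
            == "Familial chylomicronemia syndrome"
        )

    def test_no_match_returns_none(self, rules):
        findings = [make_variant(gene="LDLR")]
        assert lp.apply_diagnosis_rules(findings, "HTG", rules) is None
        assert lp.apply_diagnosis_rules([], "FH", rules) is None

    def test_phenotype_context_gates_hypobeta_rules(self, rules):
        findings = [make_variant(gene="MTTP", zygosity="homozygous")]
        assert (
            lp.apply_diagnosis_rules(findings, "hypobetalipoproteinemia", rules)
            == "Abetalipoproteinemia"
        )
        assert lp.apply_diagnosis_rules(findings, "FH", rules) is None


class TestBuildProfile:
    def test_relevance_gates_by_phenotype_gene_set(self, panel):
        rules = lp.default_diagnosis_rules(panel)
        lpl = make_variant(gene="LPL", consequence="frameshift")
        profile = lp.build_profile("S1", "FH", [lpl], [], {}, panel, rules)
        assert profile.category == "none"
        assert profile.report_category == "d_negative"

    def test_diagnosis_and_report_category(self, panel):
        rules = lp.default_diagnosis_rules(panel)
        ldlr = make_variant(gene="LDLR")
        profile = lp.build_profile("S1", "FH", [ldlr], [], {}, panel, rules)
        assert profile.category == "rare_only"
        assert profile.diagnosis == "HeFH"
        assert profile.report_category == "a_diagnosis"
        confirmed = lp.build_profile(
            "S1", "FH", [ldlr], [], {}, panel, rules, prior_diagnosis=True
        )
        assert confirmed.report_category == "b_confirmation"


class TestCohortSummary:
    def test_half_away_rounding(self):
        assert round_half_away(42.45, 1) == 42.5
        assert round_half_away(23.85, 1) == 23.9

    def test_cohort_of_one_without_findings(self):
        profiles = profiles_from_counts("FH", 0, 0, 0, 1)
        summary = lp.summarize_cohort(profiles, "FH")
        assert summary.percentages["none"] == 100.0

    def test_category_partition_and_margins(self):
        profiles = profiles_from_counts("HTG", 227, 82, 346, 653)
        summary = lp.summarize_cohort(profiles, "HTG")
        c = summary.counts
        assert c["rare_only"] + c["rare_plus_extreme"] + c["extreme_only"] + c["none"] == summary.n
        assert c["any_rare"] == c["rare_only"] + c["rare_plus_extreme"]
        assert c["any_extreme"] == c["extreme_only"] + c["rare_plus_extreme"]

    def test_empty_cohort_rejected(self):
        with pytest.raises(ProfileError, match="empty"):
            lp.summarize_cohort([], "FH")

    def test_mixed_phenotypes_rejected(self):
        profiles = profiles_from_counts("FH", 1, 0, 0, 0) + profiles_from_counts(
            "HTG", 1, 0, 0, 0
        )
        with pytest.raises(ProfileError, match="phenotype"):
            lp.summarize_cohort(profiles, "FH")
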