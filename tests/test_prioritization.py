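"""Filter-cascade predicates, the progressive cascade, and relevance rules."""

import pytest
from hypothesis import given, settings, strategies as st

import lipidpanel as lp
from lipidpanel.errors import UnknownPhenotypeError
from lipidpanel.prioritization import LOF_ONTOLOGIES, PROTEIN_ALTERING
from lipidpanel.variant_io import (
    CONSEQUENCES,
    MUTATION_TASTER_CALLS,
    POLYPHEN2_CALLS,
    SIFT_CALLS,
)

from conftest import make_variant


class TestPredicates:
    @pytest.mark.parametrize(
        "maf, expected",
        [(0.01, True), (None, True), (0.05, False), (0.0099, True), (0.011, False)],
    )
    def test_rarity_boundary_is_inclusive_and_absent_is_rare(self, maf, expected):
        assert lp.is_rare(make_variant(population_maf=maf)) is expected

    @pytest.mark.parametrize(
        "consequence, expected",
        [
            ("missense", True),
            ("splice_acceptor", True),
            ("inframe_indel", True),
            ("synonymous", False),
            ("other", False),
        ],
    )
    def test_protein_altering_ontologies(self, consequence, expected):
        assert lp.is_protein_altering(make_variant(consequence=consequence)) is expected

    @pytest.mark.parametrize(
        "consequence, expected",
        [
            ("stop_gain", True),
            ("stop_loss", True),
            ("frameshift", True),
            ("splice_donor", True),
            ("splice_acceptor", True),
            ("missense", False),
            ("inframe_indel", False),  # protein-altering but not LOF
        ],
    )
    def test_lof_ontology_set(self, consequence, expected):
        assert lp.is_lof(make_variant(consequence=consequence)) is expected

    def test_lof_is_subset_of_protein_altering(self):
        assert LOF_ONTOLOGIES < PROTEIN_ALTERING

    @pytest.mark.parametrize("consequence", sorted(CONSEQUENCES))
    @pytest.mark.parametrize("sift", SIFT_CALLS)
    @pytest.mark.parametrize("polyphen2", POLYPHEN2_CALLS)
    @pytest.mark.parametrize("mutation_taster", MUTATION_TASTER_CALLS)
    def test_deleteriousness_policy_table(
        self, consequence, sift, polyphen2, mutation_taster
    ):
        """Full enumeration against an independently written truth table."""
        v = make_variant(
            consequence=consequence,
            sift=sift,
            polyphen2=polyphen2,
            mutation_taster=mutation_taster,
        )
        lof = consequence in {
            "frameshift", "splice_acceptor", "splice_donor", "stop_gain", "stop_loss"
        }
        damaging = [
            sift == "deleterious",
            polyphen2 == "damaging",
            mutation_taster == "disease_causing",
        ]
        assert lp.is_predicted_deleterious(v, "any_tool") is (lof or any(damaging))
        assert lp.is_predicted_deleterious(v, "all_tools") is (lof or all(damaging))


def toy_six_variants():
    return [
        make_variant(position=1, consequence="missense", population_maf=0.2),
        make_variant(position=2, consequence="synonymous", population_maf=0.001),
        make_variant(
            position=3, consequence="missense", population_maf=0.001,
            sift="tolerated", polyphen2="benign", mutation_taster="polymorphism",
        ),
        make_variant(position=4, consequence="missense", population_maf=0.001),
        make_variant(position=5, consequence="frameshift", population_maf=0.001,
                     sift="unknown", polyphen2="unknown", mutation_taster="unknown"),
        make_variant(position=6, consequence="splice_donor", population_maf=None,
                     sift="unknown", polyphen2="unknown", mutation_taster="unknown"),
    ]


class TestCascade:
    def test_six_variant_toy_cascade(self):
        """Hand-evaluated: common missense, rare synonymous and rare benign
        missense drop out; damaging missense, frameshift and absent-MAF
        splice-donor survive; the truncating two are the LOF subset."""
        result = lp.run_cascade(toy_six_variants())
        assert result.stage_counts["total"] == 6
        assert result.stage_counts["rare"] == 5
        assert result.stage_counts["protein_altering"] == 4
        assert result.stage_counts["predicted_deleterious"] == 3
        survivors = {v.position for v in result.surviving["predicted_deleterious"]}
        assert survivors == {4, 5, 6}
        assert {v.position for v in result.surviving["lof"]} == {5, 6}

    def test_empty_input_gives_zero_counts(self):
        result = lp.run_cascade([])
        assert all(c == 0 for c in result.stage_counts.values())

    def test_cadd_strict_boundary_included(self):
        v20 = make_variant(position=1, cadd_phred=20.0)
        v19 = make_variant(position=2, cadd_phred=19.9)
        result = lp.run_cascade([v20, v19])
        assert {v.position for v in result.surviving["cadd_strict"]} == {1}

    def test_cascade_equals_independent_filter_composition(self):
        """Oracle: apply the three predicates independently and compare."""
        records = toy_six_variants() + [
            make_variant(position=p, consequence="stop_gain", population_maf=None)
            for p in range(10, 15)
        ]
        result = lp.run_cascade(records)
        oracle = [
            v for v in records
            if lp.is_rare(v) and lp.is_protein_altering(v)
            and lp.is_predicted_deleterious(v)
        ]
        assert result.surviving["predicted_deleterious"] == oracle


variant_strategy = st.builds(
    make_variant,
    position=st.integers(min_value=1, max_value=30),
    consequence=st.sampled_from(CONSEQUENCES),
    population_maf=st.one_of(st.none(), st.floats(0, 0.5, allow_nan=False)),
    cadd_phred=st.floats(0, 50, allow_nan=False),
    sift=st.sampled_from(SIFT_CALLS),
    polyphen2=st.sampled_from(POLYPHEN2_CALLS),
    mutation_taster=st.sampled_from(MUTATION_TASTER_CALLS),
    sample_id=st.sampled_from(["S1", "S2", "S3"]),
)


class TestCascadeProperties:
    @settings(max_examples=200, derandomize=True)
    @given(st.lists(variant_strategy, max_size=40))
    def test_stage_counts_never_increase(self, records):
        counts = list(lp.run_cascade(records).stage_counts.values())
        chain = counts[:4]  # total -> rare -> protein-altering -> deleterious
        assert all(a >= b for a, b in zip(chain, chain[1:]))
        assert counts[4] <= counts[3] and counts[5] <= counts[3]

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(variant_strategy, max_size=40))
    def test_lof_survivors_are_protein_altering_subset(self, records):
        result = lp.run_cascade(records)
        final = result.surviving["predicted_deleterious"]
        assert all(v in final for v in result.surviving["lof"])
        assert all(lp.is_protein_altering(v) for v in result.surviving["lof"])


class TestPhenotypeRelevance:
    def test_matching_gene_and_annotations_relevant(self, panel):
        v = make_variant(gene="LDLR", cadd_phred=25.0)
        assert lp.is_phenotype_relevant(v, "FH", panel)

    def test_gene_outside_phenotype_set_not_relevant(self, panel):
        v = make_variant(gene="LPL", consequence="frameshift", cadd_phred=35.0)
        assert not lp.is_phenotype_relevant(v, "FH", panel)
        assert lp.is_phenotype_relevant(v, "HTG", panel)

    @pytest.mark.parametrize("cadd, expected", [(8.0, False), (10.0, True)])
    def test_cadd_ten_floor_boundary(self, panel, cadd, expected):
        v = make_variant(gene="LDLR", cadd_phred=cadd)
        assert lp.is_phenotype_relevant(v, "FH", panel) is expected

    def test_benign_predictions_block_relevance_unless_lof(self, panel):
        benign = dict(sift="tolerated", polyphen2="benign",
                      mutation_taster="polymorphism")
        assert not lp.is_phenotype_relevant(
            make_variant(gene="LDLR", **benign), "FH", panel
        )
        assert lp.is_phenotype_relevant(
            make_variant(gene="LDLR", consequence="frameshift", **benign),
            "FH", panel,
        )

    def test_unknown_phenotype_raises(self, panel):
        with pytest.raises(UnknownPhenotypeError):
            lp.is_phenotype_relevant(make_variant(), "nope", panel)
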