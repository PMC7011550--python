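"""Depth normalization, run-based CNV calling, and unique-CNV aggregation."""

import numpy as np
import pandas as pd
import pytest

import lipidpanel as lp
from lipidpanel.cnv_caller import CnvCall, format_region
from lipidpanel.errors import CnvCallingError


def toy_matrix(depth, genes=("LDLR",), targets_per_gene=8):
    rows = []
    for gi, gene in enumerate(genes):
        labels = (
            ["5'UTR"]
            + [f"Exon {i}" for i in range(1, targets_per_gene - 1)]
            + ["3'UTR"]
        )
        for ti, label in enumerate(labels):
            rows.append(
                {
                    "gene": gene,
                    "label": label,
                    "chromosome": f"chr{gi + 1}",
                    "start": 1000 * ti + 1,
                    "end": 1000 * ti + 500,
                }
            )
    targets = pd.DataFrame(rows)
    samples = [f"S{j}" for j in range(depth.shape[1])]
    return lp.DepthMatrix(targets=targets, samples=samples, depth=depth)


def nb_depth(rng, mean, shape, size=800.0):
    mean = np.broadcast_to(mean, shape)
    return rng.negative_binomial(size, size / (size + mean)).astype(float)


class TestNormalization:
    def test_constant_matrix_normalizes_to_unit_ratios(self):
        m = toy_matrix(np.full((8, 5), 100.0))
        ratios, uncallable = lp.normalize_depth(m)
        assert np.allclose(ratios.depth, 1.0)
        assert not uncallable.any()

    def test_reference_row_mean_is_exactly_one(self):
        rng = np.random.default_rng(5)
        m = toy_matrix(nb_depth(rng, 200.0, (8, 10)))
        ratios, _ = lp.normalize_depth(m)
        assert np.allclose(ratios.depth.mean(axis=1), 1.0)

    def test_partial_deletion_shows_half_ratio(self):
        depth = np.full((8, 6), 200.0)
        depth[2:5, 0] = 100.0  # region at half depth in sample S0
        m = toy_matrix(depth)
        ratios, _ = lp.normalize_depth(m, reference_samples=[f"S{j}" for j in range(1, 6)])
        assert np.allclose(ratios.depth[2:5, 0], 0.5)
        assert np.allclose(ratios.depth[:2, 0], 1.0)

    def test_all_zero_sample_rejected(self):
        depth = np.full((8, 4), 100.0)
        depth[:, 2] = 0.0
        with pytest.raises(CnvCallingError, match="zero"):
            lp.normalize_depth(toy_matrix(depth))

    def test_zero_reference_target_flagged_uncallable(self):
        depth = np.full((8, 4), 100.0)
        depth[3, :] = 0.0
        ratios, uncallable = lp.normalize_depth(toy_matrix(depth))
        assert list(uncallable) == [False] * 3 + [True] + [False] * 4


def spiked_cohort(seed=3, n_ref=20, mult=0.5, span=slice(2, 5), n_genes=5):
    """One test sample with a depth-multiplied region (within the first gene
    of a multi-gene matrix) over negative-binomial noise."""
    rng = np.random.default_rng(seed)
    n_targets = 12 * n_genes
    shape = (n_targets, n_ref + 1)
    efficiency = np.exp(rng.normal(0, 0.3, size=n_targets))
    mean = 200.0 * efficiency[:, None] * np.ones(shape)
    mean[span, -1] *= mult
    m = toy_matrix(
        nb_depth(rng, mean, shape),
        genes=tuple(f"G{k}" for k in range(n_genes)),
        targets_per_gene=12,
    )
    refs = m.samples[:-1]
    return m, m.samples[-1], refs


class TestCalling:
    def test_het_deletion_recovered_as_single_spanning_call(self):
        m, test, refs = spiked_cohort(mult=0.5, span=slice(2, 5))
        calls = lp.call_cnvs(m, test, refs)
        assert len(calls) == 1
        call = calls[0]
        assert call.state == "het_deletion"
        assert call.target_labels == ("Exon 2", "Exon 3", "Exon 4")
        assert call.region == "Exons 2–4"

    def test_flat_matrix_yields_no_calls(self):
        m, test, refs = spiked_cohort(mult=1.0)
        assert lp.call_cnvs(m, test, refs) == []

    def test_whole_gene_duplication_spans_utr_to_utr(self):
        # many-gene matrix: a whole-gene event must stay a small fraction of
        # the panel or it perturbs the sample's own library-size median
        m, test, refs = spiked_cohort(mult=1.5, span=slice(0, 12), n_genes=20)
        calls = lp.call_cnvs(m, test, refs)
        assert [c.state for c in calls] == ["duplication"]
        assert calls[0].region == "5'UTR – 3'UTR"

    def test_homozygous_deletion_state(self):
        m, test, refs = spiked_cohort(mult=0.05, span=slice(4, 7))
        calls = lp.call_cnvs(m, test, refs)
        assert [c.state for c in calls] == ["hom_deletion"]

    def test_calls_do_not_cross_gene_boundaries(self):
        rng = np.random.default_rng(9)
        shape = (16, 21)
        mean = np.full(shape, 200.0)
        mean[6:10, -1] *= 0.5  # last 2 targets of gene A + first 2 of gene B
        m = toy_matrix(nb_depth(rng, mean, shape), genes=("A", "B"))
        calls = lp.call_cnvs(m, m.samples[-1], m.samples[:-1])
        assert sorted(c.gene for c in calls) == ["A", "B"]

    def test_invariant_to_test_library_scaling(self):
        m, test, refs = spiked_cohort(mult=0.5, span=slice(2, 5))
        scaled = lp.DepthMatrix(
            targets=m.targets, samples=m.samples, depth=m.depth.copy()
        )
        scaled.depth[:, -1] *= 1.7
        a = lp.call_cnvs(m, test, refs)
        b = lp.call_cnvs(scaled, test, refs)
        assert [(c.gene, c.region, c.state) for c in a] == [
            (c.gene, c.region, c.state) for c in b
        ]

    def test_reference_set_validation(self):
        m, test, refs = spiked_cohort()
        with pytest.raises(CnvCallingError, match="reference"):
            lp.call_cnvs(m, test, refs + [test])
        with pytest.raises(CnvCallingError, match=">= 3"):
            lp.call_cnvs(m, test, refs[:2])

    def test_deterministic_given_inputs(self):
        m, test, refs = spiked_cohort(mult=0.5)
        a = lp.call_cnvs(m, test, refs)
        b = lp.call_cnvs(m, test, refs)
        assert a == b


class TestRegionLabels:
    @pytest.mark.parametrize(
        "first, last, expected",
        [
            ("Exon 4", "Exon 4", "Exon 4"),
            ("Exon 2", "Exon 6", "Exons 2–6"),
            ("5'UTR", "Exon 1", "5'UTR – Exon 1"),
            ("Exon 16", "3'UTR", "Exon 16 – 3'UTR"),
        ],
    )
    def test_format_region(self, first, last, expected):
        assert format_region(first, last) == expected


class TestAggregation:
    def test_single_call_table(self):
        call = CnvCall("S1", "LDLR", "Exon 4", "het_deletion")
        table = lp.aggregate_unique([call])
        assert table.totals == (1, 1)
        assert table.rows[0].state_summary == "het"

    def test_distinct_breakpoint_tags_stay_distinct(self):
        calls = [
            CnvCall("S1", "LDLR", "Exons 11–12", "duplication", breakpoint_tag="a"),
            CnvCall("S2", "LDLR", "Exons 11–12", "duplication", breakpoint_tag="b"),
        ]
        assert lp.aggregate_unique(calls).totals == (2, 2)

    def test_mixed_zygosity_deletions_are_one_unique_cnv(self):
        calls = [
            CnvCall("S1", "MTTP", "Exons 10–15", "hom_deletion"),
            CnvCall("S2", "MTTP", "Exons 10–15", "hom_deletion"),
            CnvCall("S3", "MTTP", "Exons 10–15", "het_deletion"),
        ]
        table = lp.aggregate_unique(calls)
        assert table.totals == (1, 3)
        assert table.rows[0].state_summary == "hom ×2, het"

    def test_deletion_and_duplication_same_span_are_distinct(self):
        calls = [
            CnvCall("S1", "LDLR", "Exons 2–6", "het_deletion"),
            CnvCall("S2", "LDLR", "Exons 2–6", "duplication"),
        ]
        assert lp.aggregate_unique(calls).totals == (2, 2)

    def test_totals_invariant(self):
        catalogue = lp.load_cnv_catalogue()
        table = lp.aggregate_unique(catalogue)
        assert table.instance_count >= table.unique_count
        assert table.instance_count == sum(r.instances_observed for r in table.rows)

    def test_matrix_tsv_round_trip(self, tmp_path):
        m, _, _ = spiked_cohort()
        path = tmp_path / "depth.tsv"
        m.to_tsv(path)
        again = lp.DepthMatrix.from_tsv(path)
        assert again.samples == m.samples
        assert np.allclose(again.depth, m.depth)
        pd.testing.assert_frame_equal(again.targets, m.targets)
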