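"""Shared fixtures: the default panel and one synthetic cohort run end to end."""

from dataclasses import dataclass

import pytest

import lipidpanel as lp
from lipidpanel.synthetic_data import SimulationConfig


@pytest.fixture(scope="session")
def panel():
    return lp.default_panel()


@dataclass
class CohortRun:
    cfg: SimulationConfig
    reference: object
    simulation: object
    references: dict
    result: object


@pytest.fixture(scope="session")
def cohort_run(panel, tmp_path_factory) -> CohortRun:
    """A noise-free 100-patient synthetic cohort pushed through the full
    pipeline (variants + CNVs + scores -> profiles)."""
    outdir = tmp_path_factory.mktemp("cohort")
    cfg = SimulationConfig(seed=7, n_patients=100, annotation_noise_rate=0.0)
    reference = lp.simulate_reference(cfg, panel, outdir)
    simulation = lp.simulate_patients(cfg, panel, outdir, reference=reference)
    references = lp.load_references(reference.score_paths)
    result = lp.characterize_cohort(
        panel,
        simulation.vcf_path,
        simulation.annotation_path,
        simulation.depth_path,
        simulation.lipid_path,
        references,
        depth_reference_ids=simulation.depth_reference_ids,
    )
    return CohortRun(cfg, reference, simulation, references, result)


@pytest.fixture(scope="session")
def reference_10k(panel, tmp_path_factory):
    """A 10,000-sample simulated reference with per-SNP trait-raising allele
    counts extracted back out of the written VCF in one pass."""
    import numpy as np
    import pysam

    outdir = tmp_path_factory.mktemp("ref10k")
    cfg = SimulationConfig(seed=5, n_reference=10_000)
    sim = lp.simulate_reference(cfg, panel, outdir)
    by_id = {s.snp_id: s for s in panel.score_snps}
    counts = {}
    with pysam.VariantFile(str(sim.vcf_path)) as vcf:
        for rec in vcf:
            snp = by_id[rec.id]
            alleles = (rec.ref,) + tuple(rec.alts)
            raising_index = alleles.index(snp.raising_allele)
            doses = np.array(
                [
                    sum(1 for a in s.get("GT") if a == raising_index)
                    for s in rec.samples.values()
                ]
            )
            counts[rec.id] = doses
    return cfg, sim, counts


def make_variant(**overrides):
    """An AnnotatedVariant with sensible defaults, overridable per test."""
    base = dict(
        sample_id="S1",
        gene="LDLR",
        chromosome="chr19",
        position=1_001_000,
        ref_allele="A",
        alt_allele="G",
        zygosity="heterozygous",
        consequence="missense",
        population_maf=0.001,
        cadd_phred=25.0,
        sift="deleterious",
        polyphen2="damaging",
        mutation_taster="disease_causing",
    )
    base.update(overrides)
    return lp.AnnotatedVariant(**base)
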