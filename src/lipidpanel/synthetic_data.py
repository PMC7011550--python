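"""Synthetic cohort generator with known ground truth.

Emulates the data structure of a dyslipidemia sequencing program so every
pipeline stage is testable without patient data: HWE genotypes at the score
SNPs (with optional enrichment of trait-raising alleles in affected
patients), rare protein-altering variants with in-silico annotations spiked
into phenotype-relevant genes, negative-binomial per-target read depth with
embedded deletions/duplications, and lipid phenotype tables.  A TruthTable
records what was planted so recovery can be scored exactly.

What this emulates -- and what it does not: genotypes are independent across
loci (no LD), annotations are internally consistent rather than drawn from
real annotator disagreement, and depth noise is a clean negative binomial
without GC or batch structure.  Passing recovery tests therefore demonstrates
algorithmic correctness on the stated generative model, not performance on
real capture data.

All randomness flows from ``SimulationConfig.seed``; identical configs give
bit-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .errors import LipidPanelError
from .genetic_profile import PHENOTYPE_TRAIT
from .panel_model import TRAITS, PanelDefinition, phenotype_gene_set, target_regions

_LOF = ("frameshift", "stop_gain", "splice_donor", "splice_acceptor", "stop_loss")


@dataclass(frozen=True)
class CnvSpike:
    """One planted CNV: gene, target span (None = whole gene), state, carriers."""

    gene: str
    first_label: str | None
    last_label: str | None
    state: str
    n_carriers: int
    phenotype: str | None = None  # preferred carrier phenotype


def _default_mix():
    # cohort composition of the two major phenotypes, remainder unclassified
    return {"FH": 0.283, "HTG": 0.401, "unclassified": 0.316}


def _default_carrier_rates():
    # observed relevant-rare-variant carriage in the two major cohorts
    return {"FH": 0.425, "HTG": 0.239}


def _default_biallelic():
    return {"FH": 0.03, "HTG": 0.15}


def _default_enrichment():
    # odds multiplier on trait-raising alleles for the phenotype-matched trait
    return {"FH": 1.1, "HTG": 1.4}


def _default_spikes():
    return [
        CnvSpike("LDLR", "Exon 2", "Exon 6", "het_deletion", 5, "FH"),
        CnvSpike("PCSK9", None, None, "duplication", 3, "FH"),
        CnvSpike("GPIHBP1", None, None, "hom_deletion", 2, "HTG"),
    ]


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults mirror the study's cohort structure."""

    seed: int = 2020
    n_patients: int = 150
    n_reference: int = 503
    phenotype_mix: dict = field(default_factory=_default_mix)
    rare_variant_carrier_rate: dict = field(default_factory=_default_carrier_rates)
    biallelic_carrier_fraction: dict = field(default_factory=_default_biallelic)
    extreme_enrichment: dict = field(default_factory=_default_enrichment)
    depth_mean: float = 200.0
    depth_dispersion: float = 800.0  # NB size; variance = m * (1 + m/size)
    n_depth_reference: int = 20
    cnv_spike_list: list = field(default_factory=_default_spikes)
    annotation_noise_rate: float = 0.02
    n_common_fodder: int = 25
    n_rare_benign_fodder: int = 15

    def __post_init__(self):
        total = sum(self.phenotype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise LipidPanelError(f"phenotype_mix fractions sum to {total}, not 1")


@dataclass
class TruthRecord:
    sample_id: str
    phenotype: str
    scores: dict  # trait -> raw score
    extreme: dict  # trait -> bool
    variants: list  # dicts: gene, zygosity, consequence, chrom, pos, ref, alt
    cnvs: list  # dicts: gene, region, state
    category: str
    diagnosis: str | None


@dataclass
class TruthTable:
    records: dict  # sample_id -> TruthRecord

    def to_json(self, path) -> None:
        payload = {sid: asdict(rec) for sid, rec in sorted(self.records.items())}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class ReferenceSimulation:
    vcf_path: Path
    score_paths: dict  # trait -> TSV path
    scores: dict  # trait -> np.ndarray


@dataclass
class PatientSimulation:
    vcf_path: Path
    annotation_path: Path
    depth_path: Path
    lipid_path: Path
    truth_path: Path
    truth: TruthTable
    patient_ids: list
    depth_reference_ids: list


# ---------------------------------------------------------------------------
# VCF writing


def _chrom_sort_key(name: str):
    core = name.replace("chr", "")
    return (0, int(core)) if core.isdigit() else (1, core)


def _write_vcf(path, sample_ids, sites):
    """Write a plain VCF.  ``sites``: dicts with chrom,pos,id,ref,alt and
    ``alt_counts`` (array of per-sample alt-allele doses 0/1/2)."""
    header = pysam.VariantHeader()
    for chrom in sorted({s["chrom"] for s in sites}, key=_chrom_sort_key):
        header.contigs.add(chrom, length=600_000_000)
    header.formats.add("GT", 1, "String", "Genotype")
    for sid in sample_ids:
        header.add_sample(sid)
    gt_of = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for site in sorted(sites, key=lambda s: (_chrom_sort_key(s["chrom"]), s["pos"])):
            rec = vcf.new_record(
                contig=site["chrom"],
                start=site["pos"] - 1,
                stop=site["pos"] - 1 + len(site["ref"]),
                alleles=(site["ref"], site["alt"]),
            )
            rec.id = site["id"]
            for j, sid in enumerate(sample_ids):
                rec.samples[sid]["GT"] = gt_of[int(site["alt_counts"][j])]
            vcf.write(rec)
    return Path(path)


def _hwe_raising_counts(rng, freq: float, n: int) -> np.ndarray:
    return rng.binomial(2, freq, size=n)


def _boost_odds(freq: float, multiplier: float) -> float:
    odds = multiplier * freq / (1.0 - freq)
    return odds / (1.0 + odds)


def _score_sites(panel, raising_counts: dict) -> list:
    """Score-SNP VCF sites; the trait-raising allele alternates between the
    REF and ALT column so orientation handling gets exercised."""
    sites = []
    for i, snp in enumerate(panel.score_snps):
        raising_is_alt = i % 2 == 0
        counts = raising_counts[snp.snp_id]
        sites.append(
            {
                "chrom": snp.chromosome,
                "pos": snp.position,
                "id": snp.snp_id,
                "ref": snp.other_allele if raising_is_alt else snp.raising_allele,
                "alt": snp.raising_allele if raising_is_alt else snp.other_allele,
                "alt_counts": counts if raising_is_alt else 2 - counts,
            }
        )
    return sites


def _raw_scores(panel, trait, raising_counts: dict) -> np.ndarray:
    snps = panel.score_snps_for(trait)
    total = None
    for snp in snps:
        term = raising_counts[snp.snp_id] * snp.beta
        total = term if total is None else total + term
    return total


def _nearest_rank_threshold(scores: np.ndarray, q: float = 90.0) -> float:
    ordered = np.sort(scores)
    rank = max(math.ceil(q / 100.0 * ordered.size), 1)
    return float(ordered[rank - 1])


# ---------------------------------------------------------------------------
# reference cohort


def simulate_reference(
    cfg: SimulationConfig, panel: PanelDefinition, outdir
) -> ReferenceSimulation:
    """Normolipidemic reference cohort: HWE score-SNP genotypes, no rare
    variants, no CNVs.  Writes a VCF and one raw-score TSV per trait."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([cfg.seed, 11])
    sample_ids = [f"REF{i + 1:04d}" for i in range(cfg.n_reference)]
    raising = {
        snp.snp_id: _hwe_raising_counts(rng, snp.raising_allele_freq, cfg.n_reference)
        for snp in panel.score_snps
    }
    vcf_path = _write_vcf(outdir / "reference.vcf", sample_ids, _score_sites(panel, raising))
    scores = {}
    score_paths = {}
    for trait in TRAITS:
        scores[trait] = _raw_scores(panel, trait, raising)
        path = outdir / f"reference_scores_{trait}.tsv"
        pd.DataFrame({"score": scores[trait]}).to_csv(path, sep="\t", index=False)
        score_paths[trait] = path
    return ReferenceSimulation(vcf_path=vcf_path, score_paths=score_paths, scores=scores)


# ---------------------------------------------------------------------------
# patient cohort


def _draw_phenotypes(rng, cfg) -> list:
    keys = sorted(cfg.phenotype_mix)
    probs = np.array([cfg.phenotype_mix[k] for k in keys])
    return [keys[i] for i in rng.choice(len(keys), size=cfg.n_patients, p=probs)]


_OTHER_BASE = {"A": "G", "C": "T", "G": "A", "T": "C"}


def _spike_causal_variant(rng, gene, zygosity, position):
    """A phenotype-concordant causal variant: protein-altering, rare,
    CADD >= 10, and damaging by at least one tool (or LOF)."""
    if rng.random() < 0.6:
        consequence = "missense"
        sift = "deleterious" if rng.random() < 0.8 else "unknown"
        polyphen2 = "damaging" if rng.random() < 0.8 else "unknown"
        mt = "disease_causing" if rng.random() < 0.7 else "unknown"
        if sift != "deleterious" and polyphen2 != "damaging" and mt != "disease_causing":
            sift = "deleterious"
    else:
        consequence = str(rng.choice(_LOF))
        sift = polyphen2 = mt = "unknown"
    ref = str(rng.choice(list("ACGT")))
    alt = _OTHER_BASE[ref]
    maf = None if rng.random() < 0.5 else float(np.round(rng.uniform(0.0001, 0.005), 5))
    return {
        "gene": gene.symbol,
        "chrom": gene.chromosome,
        "pos": position,
        "ref": ref,
        "alt": alt,
        "consequence": consequence,
        "maf": maf,
        "cadd_phred": float(np.round(rng.uniform(12.0, 38.0), 1)),
        "sift": sift,
        "polyphen2": polyphen2,
        "mutation_taster": mt,
        "zygosity": zygosity,
    }


def _fodder_site(rng, gene, position, rare: bool):
    if rng.random() < 0.5:
        consequence, sift, pp2, mt = "synonymous", "unknown", "unknown", "unknown"
    else:
        consequence, sift, pp2, mt = "missense", "tolerated", "benign", "polymorphism"
    ref = str(rng.choice(list("ACGT")))
    if rare:
        maf = None if rng.random() < 0.3 else float(np.round(rng.uniform(0.0001, 0.009), 5))
    else:
        maf = float(np.round(rng.uniform(0.02, 0.40), 4))
    return {
        "gene": gene.symbol,
        "chrom": gene.chromosome,
        "pos": position,
        "ref": ref,
        "alt": _OTHER_BASE[ref],
        "consequence": consequence,
        "maf": maf,
        "cadd_phred": float(np.round(rng.uniform(0.0, 9.5), 1)),
        "sift": sift,
        "polyphen2": pp2,
        "mutation_taster": mt,
    }


def _exon_position(gene, counter: int) -> int:
    ivs = gene.intervals[1:-1] if len(gene.intervals) > 2 else gene.intervals
    iv = ivs[counter % len(ivs)]
    return iv[0] + (counter * 7) % (iv[1] - iv[0] + 1)


def _mirror_diagnosis(phenotype: str, gene_dose: dict) -> str | None:
    """Generator-side diagnosis truth, mirroring the shipped rule table for
    the phenotypes this generator produces."""
    def biallelic_in(genes):
        return any(gene_dose.get(g, 0) >= 2 for g in genes)

    def het_in(genes):
        return any(gene_dose.get(g, 0) == 1 for g in genes)

    if phenotype == "FH":
        if biallelic_in(["LDLR", "APOB", "PCSK9", "LDLRAP1"]):
            return "HoFH"
        if het_in(["LDLR", "APOB", "PCSK9"]):
            return "HeFH"
    if phenotype in ("HTG", "severe_HTG"):
        if biallelic_in(["APOC2"]):
            return "APOC2 deficiency"
        if biallelic_in(["LPL", "APOA5", "GPIHBP1", "LMF1"]):
            return "Familial chylomicronemia syndrome"
    return None


def simulate_patients(
    cfg: SimulationConfig, panel: PanelDefinition, outdir,
    reference: ReferenceSimulation | None = None,
) -> PatientSimulation:
    """Generate the patient cohort: VCF + annotation TSV, depth matrix,
    lipid table, and the TruthTable.

    If ``reference`` is given, truth extreme-score flags are classified
    against its score distributions (nearest-rank 90th percentile);
    otherwise all truth extreme flags are False.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([cfg.seed, 23])
    n = cfg.n_patients
    patient_ids = [f"P{i + 1:04d}" for i in range(n)]
    phenotypes = _draw_phenotypes(rng, cfg)

    # --- score-SNP genotypes, with trait-raising enrichment per phenotype
    raising: dict[str, np.ndarray] = {}
    for snp in panel.score_snps:
        counts = np.empty(n, dtype=int)
        for i, pheno in enumerate(phenotypes):
            freq = snp.raising_allele_freq
            mult = cfg.extreme_enrichment.get(pheno, 1.0)
            if mult != 1.0 and PHENOTYPE_TRAIT.get(pheno) == snp.trait:
                freq = _boost_odds(freq, mult)
            counts[i] = rng.binomial(2, freq)
        raising[snp.snp_id] = counts
    sites = _score_sites(panel, raising)

    scores = {trait: _raw_scores(panel, trait, raising) for trait in TRAITS}
    thresholds = {
        trait: (
            _nearest_rank_threshold(reference.scores[trait])
            if reference is not None
            else math.inf
        )
        for trait in TRAITS
    }

    # --- rare causal variants (one per carrier, phenotype-concordant gene)
    truth_variants: dict[str, list] = {sid: [] for sid in patient_ids}
    position_counter = 0
    causal_sites = []
    for i, (sid, pheno) in enumerate(zip(patient_ids, phenotypes)):
        rate = cfg.rare_variant_carrier_rate.get(pheno, 0.0)
        if rng.random() >= rate:
            continue
        genes = sorted(phenotype_gene_set(panel, pheno))
        if not genes:
            continue
        gene = panel.gene(str(rng.choice(genes)))
        zygosity = (
            "homozygous"
            if rng.random() < cfg.biallelic_carrier_fraction.get(pheno, 0.0)
            else "heterozygous"
        )
        position_counter += 1
        var = _spike_causal_variant(
            rng, gene, zygosity, _exon_position(gene, position_counter)
        )
        alt_counts = np.zeros(n, dtype=int)
        alt_counts[i] = 2 if zygosity == "homozygous" else 1
        causal_sites.append(
            {
                "chrom": var["chrom"],
                "pos": var["pos"],
                "id": f"var{position_counter:04d}",
                "ref": var["ref"],
                "alt": var["alt"],
                "alt_counts": alt_counts,
                "annotation": var,
            }
        )
        truth_variants[sid].append(
            {
                "gene": var["gene"],
                "zygosity": zygosity,
                "consequence": var["consequence"],
                "chrom": var["chrom"],
                "pos": var["pos"],
                "ref": var["ref"],
                "alt": var["alt"],
            }
        )

    # --- benign/common filter fodder
    fodder_sites = []
    all_genes = panel.genes
    for k in range(cfg.n_common_fodder + cfg.n_rare_benign_fodder):
        rare = k >= cfg.n_common_fodder
        gene = all_genes[int(rng.integers(len(all_genes)))]
        position_counter += 1
        site = _fodder_site(rng, gene, _exon_position(gene, position_counter), rare)
        if rare:
            alt_counts = (rng.random(n) < 0.02).astype(int)
        else:
            alt_counts = rng.binomial(2, site["maf"], size=n)
        fodder_sites.append(
            {
                "chrom": site["chrom"],
                "pos": site["pos"],
                "id": f"fod{k:03d}",
                "ref": site["ref"],
                "alt": site["alt"],
                "alt_counts": alt_counts,
                "annotation": site,
            }
        )

    # --- annotation table (score SNPs annotated as non-coding common SNPs)
    ann_rows = []
    for site in sites:
        snp = next(s for s in panel.score_snps if s.snp_id == site["id"])
        maf = round(min(snp.raising_allele_freq, 1 - snp.raising_allele_freq), 6)
        ann_rows.append(
            {
                "chrom": site["chrom"],
                "pos": site["pos"],
                "ref": site["ref"],
                "alt": site["alt"],
                "gene": "micro_seq",
                "consequence": "other",
                "maf": maf,
                "cadd_phred": 0.0,
                "sift": "unknown",
                "polyphen2": "unknown",
                "mutation_taster": "unknown",
            }
        )
    flip = {
        "deleterious": "tolerated", "tolerated": "deleterious",
        "damaging": "benign", "benign": "damaging",
        "disease_causing": "polymorphism", "polymorphism": "disease_causing",
        "unknown": "unknown",
    }
    for site in causal_sites + fodder_sites:
        ann = site["annotation"]
        row = {
            "chrom": ann["chrom"],
            "pos": ann["pos"],
            "ref": ann["ref"],
            "alt": ann["alt"],
            "gene": ann["gene"],
            "consequence": ann["consequence"],
            "maf": ann["maf"],
            "cadd_phred": ann["cadd_phred"],
            "sift": ann["sift"],
            "polyphen2": ann["polyphen2"],
            "mutation_taster": ann["mutation_taster"],
        }
        if rng.random() < cfg.annotation_noise_rate:
            row["sift"] = flip[row["sift"]]
            row["polyphen2"] = flip[row["polyphen2"]]
            row["mutation_taster"] = flip[row["mutation_taster"]]
            row["cadd_phred"] = float(np.round(row["cadd_phred"] * rng.uniform(0.6, 1.4), 1))
        ann_rows.append(row)
    annotation_path = outdir / "patients_annotation.tsv"
    ann_frame = pd.DataFrame(ann_rows)
    ann_frame.to_csv(annotation_path, sep="\t", index=False, na_rep="NA")

    vcf_path = _write_vcf(
        outdir / "patients.vcf",
        patient_ids,
        sites + [dict(s, annotation=None) for s in causal_sites + fodder_sites],
    )

    # --- depth matrix with embedded CNVs
    targets = target_regions(panel)
    ref_ids = [f"REFD{i + 1:03d}" for i in range(cfg.n_depth_reference)]
    depth_samples = ref_ids + patient_ids
    n_targets = len(targets)
    efficiency = np.exp(rng.normal(0.0, 0.3, size=n_targets))
    library = np.exp(rng.normal(0.0, 0.15, size=len(depth_samples)))
    multiplier = np.ones((n_targets, len(depth_samples)))

    state_mult = {"het_deletion": 0.5, "hom_deletion": 0.05, "duplication": 1.5}
    truth_cnvs: dict[str, list] = {sid: [] for sid in patient_ids}
    gene_rows = {g: list(idx) for g, idx in targets.groupby("gene", sort=False).groups.items()}
    carrier_cursor: dict[str, int] = {}
    for spike in cfg.cnv_spike_list:
        if spike.gene not in gene_rows:
            raise LipidPanelError(f"CNV spike gene {spike.gene!r} not in panel")
        rows = gene_rows[spike.gene]
        labels = [targets.at[r, "label"] for r in rows]
        if spike.first_label is None:
            span = rows
            region = f"{labels[0]} – {labels[-1]}"
        else:
            try:
                a = labels.index(spike.first_label)
                b = labels.index(spike.last_label)
            except ValueError as exc:
                raise LipidPanelError(
                    f"CNV spike region {spike.first_label}..{spike.last_label} "
                    f"not in {spike.gene} targets"
                ) from exc
            span = rows[a : b + 1]
            from .cnv_caller import format_region

            region = format_region(labels[a], labels[b])
        eligible = [
            i for i, p in enumerate(phenotypes)
            if spike.phenotype is None or p == spike.phenotype
        ] or list(range(len(patient_ids)))
        start = carrier_cursor.get(spike.phenotype or "*", 0)
        chosen = [eligible[(start + k) % len(eligible)] for k in range(spike.n_carriers)]
        carrier_cursor[spike.phenotype or "*"] = start + spike.n_carriers
        for i in chosen:
            col = len(ref_ids) + i
            for r in span:
                multiplier[r, col] *= state_mult[spike.state]
            truth_cnvs[patient_ids[i]].append(
                {"gene": spike.gene, "region": region, "state": spike.state}
            )

    mean = (
        cfg.depth_mean * efficiency[:, None] * library[None, :] * multiplier
    )
    size = cfg.depth_dispersion
    depth = rng.negative_binomial(size, size / (size + mean)).astype(float)
    from .cnv_caller import DepthMatrix

    depth_path = outdir / "depth_matrix.tsv"
    DepthMatrix(targets=targets, samples=depth_samples, depth=depth).to_tsv(depth_path)

    # --- lipid table (referral phenotype carried alongside)
    lipid_rows = []
    for i, (sid, pheno) in enumerate(zip(patient_ids, phenotypes)):
        z_ldl = scores["LDL"][i] - float(np.mean(scores["LDL"]))
        z_tg = scores["TG"][i] - float(np.mean(scores["TG"]))
        carrier = 1.0 if truth_variants[sid] or truth_cnvs[sid] else 0.0
        if pheno == "FH":
            ldl = float(np.clip(rng.normal(6.2, 0.8) + 0.6 * carrier + 0.5 * z_ldl, 5.05, 12.0))
            tg = float(np.clip(rng.normal(1.2, 0.3), 0.3, 1.75))
        elif pheno == "HTG":
            ldl = float(np.clip(rng.normal(3.2, 0.7), 0.8, 4.95))
            tg = float(np.clip(np.exp(rng.normal(1.1, 0.4)) + 1.5 * carrier + 1.0 * z_tg, 1.85, 9.8))
        else:
            ldl = float(np.clip(rng.normal(3.0, 0.6), 0.8, 4.9))
            tg = float(np.clip(np.exp(rng.normal(0.1, 0.3)), 0.3, 1.75))
        hdl = float(np.clip(rng.normal(1.2, 0.3), 0.4, 3.0))
        lipid_rows.append(
            {
                "sample_id": sid,
                "referral_phenotype": pheno,
                "total_chol": round(ldl + hdl + 0.45 * tg, 2),
                "ldl_chol": round(ldl, 2),
                "hdl_chol": round(hdl, 2),
                "triglyceride": round(tg, 2),
                "lpa": round(float(np.clip(np.exp(rng.normal(2.2, 1.0)), 0.5, 200.0)), 1),
            }
        )
    lipid_path = outdir / "lipids.tsv"
    pd.DataFrame(lipid_rows).to_csv(lipid_path, sep="\t", index=False)

    # --- truth table
    records = {}
    for i, (sid, pheno) in enumerate(zip(patient_ids, phenotypes)):
        extreme = {
            trait: bool(scores[trait][i] >= thresholds[trait]) for trait in TRAITS
        }
        matched_trait = PHENOTYPE_TRAIT.get(pheno)
        matched_extreme = extreme.get(matched_trait, False) if matched_trait else False
        has_rare = bool(truth_variants[sid] or truth_cnvs[sid])
        if has_rare and matched_extreme:
            category = "rare_plus_extreme"
        elif has_rare:
            category = "rare_only"
        elif matched_extreme:
            category = "extreme_only"
        else:
            category = "none"
        gene_dose: dict[str, int] = {}
        for v in truth_variants[sid]:
            gene_dose[v["gene"]] = gene_dose.get(v["gene"], 0) + (
                2 if v["zygosity"] == "homozygous" else 1
            )
        for c in truth_cnvs[sid]:
            gene_dose[c["gene"]] = gene_dose.get(c["gene"], 0) + (
                2 if c["state"] == "hom_deletion" else 1
            )
        records[sid] = TruthRecord(
            sample_id=sid,
            phenotype=pheno,
            scores={t: float(scores[t][i]) for t in TRAITS},
            extreme=extreme,
            variants=truth_variants[sid],
            cnvs=truth_cnvs[sid],
            category=category,
            diagnosis=_mirror_diagnosis(pheno, gene_dose),
        )
    truth = TruthTable(records=records)
    truth_path = outdir / "truth.json"
    truth.to_json(truth_path)

    return PatientSimulation(
        vcf_path=vcf_path,
        annotation_path=annotation_path,
        depth_path=depth_path,
        lipid_path=lipid_path,
        truth_path=truth_path,
        truth=truth,
        patient_ids=patient_ids,
        depth_reference_ids=ref_ids,
    )
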