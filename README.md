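# lipidpanel

Targeted-panel genetics of dyslipidemia: a reusable implementation of the
analytic pathway behind hybrid clinical sequencing panels for lipid
disorders, for laboratories and methodologists who want the full path from
annotated variants to a patient-facing genetic report in auditable,
testable code.

Dyslipidemias — extreme deviations of plasma lipids such as LDL
cholesterol, triglyceride, or HDL cholesterol — have two broad genetic
architectures: **monogenic** forms driven by rare large-effect variants
(SNVs, indels, or copy-number variants) in established causal genes, and
**polygenic** forms driven by an unlucky accumulation of common
trait-raising alleles of small effect. A hybrid targeted panel addresses
both at once: deep coverage of 69 genes (causative for monogenic
dyslipidemias, lipodystrophies, and MODY diabetes, plus candidate genes)
enables rare-variant and CNV detection, while micro-sequenced GWAS SNPs
support small weighted polygenic scores.

## What the package computes

**Rare-variant prioritization** — the progressive filter cascade

> keep *v* iff MAF(*v*) ≤ 0.01 or absent → consequence(*v*) ∈
> protein-altering ontologies → damaging by ≥ 1 of SIFT / PolyPhen2 /
> MutationTaster, or a LOF ontology

with unique-variant counts per stage and two subsets of the survivors:
LOF ontologies (frameshift, splice acceptor/donor, stop gain/loss) and the
stricter CADD PHRED ≥ 20 tier.

**Read-depth CNV calling** — a test sample against a panel of CNV-free
reference samples. After library-size and target-efficiency normalization,
each target's diploid-relative ratio and z-score

&nbsp;&nbsp;&nbsp;&nbsp;*z*ₜ = (*r*ₜ − mean_ref(*r*ₜ)) / sd_ref(*r*ₜ)

feed a run-based caller: maximal runs of targets in one copy-state band
(het deletion ≈ 0.5, hom deletion ≈ 0, duplication ≈ 1.5) with per-target
|*z*| ≥ 3 and run-level |Σ*z*|/√len ≥ 6. Calls aggregate into a
unique-CNV catalogue keyed by (gene, region, deletion/duplication,
breakpoint tag).

**Polygenic scores** — for each trait, PS = Σᵢ *g*ᵢ·βᵢ over the trait's
score SNPs (10 LDL, 16 TG, 9 HDL), where *g*ᵢ ∈ {0,1,2} counts
trait-raising alleles and βᵢ is the GWAS effect weight. A score is
**extreme** when it reaches the 90th percentile (nearest-rank, inclusive)
of a normolipidemic reference cohort (N = 503 by default).

**Genetic profiling and reporting** — phenotype-relevant findings (rare
protein-altering variants with CADD ≥ 10 and a damaging call or LOF
ontology, in the phenotype's causal genes; plus CNVs in those genes) and
the phenotype-matched extreme-score flag combine into a four-way profile:
*rare variant only*, *rare variant + extreme PS*, *extreme PS only*, or
*no relevant determinant*. Ordered gene/zygosity rules then assign
diagnoses (heterozygous LDLR/APOB/PCSK9 → HeFH; biallelic → HoFH;
biallelic LPL/APOC2/APOA5/GPIHBP1/LMF1 → familial chylomicronemia
syndrome; …), and per-patient reports disclose only the score matching the
referral phenotype, as both the weighted score and a simple allele tally.

**Synthetic cohorts** — a generator with exact ground truth (HWE score-SNP
genotypes with optional trait-raising enrichment, phenotype-concordant
rare-variant spike-ins with in-silico annotations, negative-binomial depth
matrices with embedded CNVs, lipid tables) so the whole pipeline is
testable without patient data, which for the real cohorts cannot be
shared. Shipped gene coordinates and score-SNP weights are synthetic
placeholders.

## Worked example

Simulate a 30-patient cohort and run the pipeline from the shell:

```bash
lipidpanel simulate --seed 5 --n-patients 30 --out demo
cd demo
lipidpanel filter patients_annotation.tsv --vcf patients.vcf --out filt
lipidpanel report --vcf patients.vcf --annotation patients_annotation.tsv \
    --depth depth_matrix.tsv --lipids lipids.tsv --reference-dir . \
    --sample P0001 --out reports
```

The `filter` step prints the cascade:

```
total: 74 unique variants
rare: 14 unique variants
protein_altering: 11 unique variants
predicted_deleterious: 8 unique variants
lof: 5 unique variants
cadd_strict: 6 unique variants
```

74 distinct variants were seen across the cohort; 14 are rare (MAF ≤ 1% or
absent), 11 of those alter the protein, and 8 survive the in-silico
deleteriousness screen — 5 with LOF ontologies and 6 at CADD ≥ 20.

`reports/P0001.txt` then reads:

```
GENETIC REPORT — sample P0001
Referral phenotype: HTG
Outcome: A genetically based diagnosis
Diagnosis: Familial chylomicronemia syndrome

Rare variant findings:
  - GPIHBP1: deletion of 5'UTR – 3'UTR, homozygous [copy_number_variant]

Polygenic score (TG):
  weighted score 1.1647 over 16 SNPs
  trait-raising allele tally: 15
  reference percentile: 89.7 — not extreme
```

This patient, referred for hypertriglyceridemia, carries a homozygous
whole-gene deletion of *GPIHBP1* — recovered by the CNV caller from the
depth matrix — which the diagnosis rules map to familial chylomicronemia
syndrome. Their triglyceride polygenic score (1.16 trait units, 15 raising
alleles across 16 loci) sits at the 89.7th reference percentile, just
under the extreme threshold, so only the rare-variant finding drives the
report. The same computations are available as library calls
(`lipidpanel.run_cascade`, `lipidpanel.call_cnvs`,
`lipidpanel.characterize_cohort`, …).

## Layout

| module | contents |
| --- | --- |
| `panel_model` | panel config (gene targets, score SNPs), phenotype→gene sets, BED export |
| `variant_io` | VCF + annotation-TSV ingestion, unique-variant keys |
| `prioritization` | rarity / protein-altering / deleteriousness predicates, filter cascade |
| `cnv_caller` | depth normalization, run-based calling, unique-CNV aggregation |
| `polygenic_score` | weighted scores, allele tallies, percentiles, extreme classification |
| `genetic_profile` | phenotype assignment, 4-way profiles, diagnosis rules, cohort summaries |
| `report` | per-patient JSON/text reports with disclosure rules |
| `synthetic_data` | ground-truthed cohort generator |
| `pipeline`, `cli` | orchestration and the `lipidpanel` command |

See `docs/methods.md` for the model and its assumptions, parameter
defaults, and known limitations.
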