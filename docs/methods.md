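# Methods

This note documents the models and procedures implemented in `lipidpanel`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not establish.

## Panel model

A panel is config data, not code: a gene table (symbol, category,
chromosome, 1-based inclusive target intervals, phenotype links,
inheritance) and a score-SNP table (id, trait, trait-raising allele, beta
weight in trait units per allele, raising-allele population frequency).
The shipped default carries 69 genes — 25 monogenic-dyslipidemia, 16
lipodystrophy, 13 MODY/inherited-diabetes, 15 candidate — and 35 score
SNPs (10 LDL, 16 TG, 9 HDL) out of 185 micro-sequenced loci.
Real per-SNP identities and GWAS weights are external data, so the shipped
coordinates, rsID-style identifiers, betas, and frequencies are **synthetic
placeholders**; every computation treats them as ordinary inputs, and a
laboratory would substitute its own tables. Interval bookkeeping is
1-based inclusive internally, converted to 0-based half-open only on BED
export. Within a gene, targets are labeled 5'UTR, Exon 1…k, 3'UTR in
genomic order; these labels are the vocabulary for CNV region strings.

Phenotype→gene lookups are stored on the gene records (e.g. FH →
{LDLR, APOB, PCSK9}; hypertriglyceridemia → {LPL, APOA5, LMF1, GPIHBP1,
APOC2}; lipodystrophy → {LMNA, PPARG}; MODY → {HNF1A, GCK};
hypoalphalipoproteinemia → {LCAT, APOA1, ABCA1}), so alternative gene
ontologies are a config edit, not a code change.

## Rare-variant prioritization

Three predicates compose the cascade, applied in order, with counts
reported as **unique variants** (deduplicated across samples by
chrom/pos/ref/alt):

1. **rare**: population MAF ≤ 0.01, or absent from population databases.
   Absence is a distinct marker (`NA` on disk, `None` in memory), never
   0.0 — an absent variant is rare by definition, and conflating it with
   an observed frequency of zero would make the filter's behavior depend
   on serialization details. The boundary (exactly 1%) passes.
2. **protein-altering**: consequence ∈ {missense, stop gain, stop loss,
   frameshift, in-frame indel, splice acceptor, splice donor}. In-frame
   indels alter the protein but are *not* LOF.
3. **predicted deleterious**: at least one damaging call among SIFT
   ("deleterious"), PolyPhen2 ("damaging"), MutationTaster
   ("disease_causing") — or a LOF ontology, which bypasses the tools
   entirely because missense-oriented predictors do not score truncating
   variants. The disjunctive (any-tool) policy is the default; a
   conjunctive all-tools policy is available for sensitivity analysis, in
   which an `unknown` call fails the conjunction.

Two subsets of the final survivors are reported: LOF-ontology variants,
and variants at CADD PHRED ≥ 20 (boundary included), the tier most likely
to be clinically actionable.

A separate **phenotype-relevance** rule gates what counts as a reportable
finding for a given referral phenotype: gene in the phenotype's causal
set, rare, protein-altering, CADD PHRED ≥ 10, and ≥ 1 damaging tool call
or LOF ontology.

## CNV calling

The caller compares one test sample's per-target mean read depth to ≥ 3
(typically 20) CNV-free reference samples.

**Normalization** is two-step: every sample column is scaled to the grand
median of column medians (library-size correction), then every target row
is divided by its mean over the reference samples (target-efficiency
correction). Diploid targets then sit at ratio ≈ 1 by construction, and
the reference-row mean of normalized ratios is exactly 1. Targets whose
reference depth is zero are uncallable. A consequence worth stating
plainly: calling is invariant to uniform scaling of the test sample's
library — a sample sequenced at uniformly half depth is indistinguishable
from a half-size library and produces no calls. Only depth changes
*relative to the sample's own median* are visible, which is the correct
behavior for events spanning a small fraction of the panel and the reason
a whole-panel aneuploidy would be invisible (documented limitation).

**Calling** assigns each callable target a state from its ratio *r* and
z-score against the reference distribution: hom deletion (*r* < 0.15),
het deletion (0.35 ≤ *r* ≤ 0.65), duplication (1.35 ≤ *r* ≤ 1.75), each
also requiring |z| ≥ `z_min` (default 3). Maximal runs of same-state
targets within a gene become calls if the run has ≥ `min_targets`
(default 1, since single-exon events are real) and passes a run-level
combined-evidence threshold |Σz|/√len ≥ `z_combined` (default 6). The
combined threshold exists because a per-target |z| ≥ 3 rule alone, applied
across ~700 panel targets, would emit on the order of one spurious
single-exon call per sample; Stouffer-style combination lets single-exon
calls demand strong evidence while long events accumulate it. Runs may
bridge up to `gap_tolerance` (default 1) consecutive interior targets that
fail state assignment — at a true 1.5× duplication the band's lower edge
lies only ~1.5 SD from the expected ratio, so long events would otherwise
split mid-run about half the time — but a target assigned a *different*
state always breaks the run. All thresholds live in `CallerParams`.

Power at the defaults (200× mean depth, negative-binomial depth with
variance 1.25× Poisson, 20 reference samples): a heterozygous deletion
shifts a target by ~5–7 reference SD, so multi-target events are recovered
essentially always, and the measured false-positive rate on null cohorts
is below one call per 50 samples. Single-exon events need |z| ≥ 6 on one
target: reliably reached by homozygous deletions, usually by het deletions
on well-behaved targets, marginal for duplications on noisy ones.

**Unique-CNV aggregation** groups calls by (gene, region, copy direction,
breakpoint tag). Heterozygous and homozygous observations of the same
deletion are one unique CNV whose zygosity breakdown is kept as a summary
("hom ×2, het"); deletions and duplications of the same span are distinct;
same-span events with different breakpoint tags are distinct. Breakpoint
tags cannot come from depth alone — they carry upstream evidence or
simulation truth — a documented limitation of read-depth calling. The
package ships an instance-level catalogue of published unique-CNV
observations (191 instances) as a fixture for this aggregation, which
collapses it to 77 unique events.

## Polygenic scores

PS = Σ gᵢβᵢ over the trait's score SNPs, gᵢ ∈ {0,1,2} trait-raising
alleles. Missing genotypes contribute zero and are excluded from
`n_snps_used`, so a low-coverage score is detectable downstream; no
imputation is attempted. VCF extraction orients counts to the
trait-raising allele whether it is REF or ALT. The unweighted allele
tally is computed alongside, because patients grasp "15 of a possible 32
raising alleles" more readily than a weighted sum.

Percentiles against the normolipidemic reference are empirical
nearest-rank: the q-th percentile is the ⌈qn/100⌉-th order statistic, and
a score is **extreme** iff it is ≥ that realized reference value
(inclusive, per the "greater than or equal to the 90th percentile" rule).
No interpolation — the threshold is always a value the reference actually
contains, and self-scoring the reference flags a fraction in
[0.10, 0.10 + 1/n]. Whether interpolation was used upstream historically
is not documented; nearest-rank is this package's declared choice. The
reference distribution is an input file (default synthetic, N = 503,
mirroring the size of the European 1000-Genomes subgroup used as the
normolipidemic reference in practice), never a hard-coded constant.

## Genetic profiles, diagnoses, reports

Lipid thresholds (mmol/L; Lp(a) mg/dL): severe hypertriglyceridemia
TG ≥ 10; hypertriglyceridemia TG ≥ 1.8; suspected FH LDL > 5.0 (strict);
elevated Lp(a) ≥ 36; combined LDL and TG elevation → familial combined
hyperlipidemia. Assignment is precedence-ordered (severe HTG > combined >
FH > HTG > high Lp(a) > unclassified) and total; a referral phenotype in
the input always overrides the computed one, since referral reflects
clinical context the lipid numbers alone cannot. Unit conversions:
×38.67 (cholesterol), ×88.57 (triglyceride) from mmol/L to mg/dL.

The four-way profile is the cross of {any relevant rare finding} ×
{phenotype-matched extreme score}. CNVs in phenotype genes count as rare
findings. Diagnosis rules are an ordered config list (first match wins)
of (phenotype context, gene set, required allelic state, label),
shipped as JSON. Allelic state from unphased data: SNV doses sum (two
heterozygous variants in one gene are presumed in trans — an over-call
risk that cannot be resolved without phasing); CNV calls contribute the
largest single-call dose per gene (a split or tandem event is one allele);
a het SNV plus a het deletion is compound heterozygous. Report categories:
(a) new genetically based diagnosis, (b) confirmation when a prior
clinical suspicion flag is set, (c) relevant finding without a rule-based
diagnosis, (d) negative. Only the phenotype-matched trait's score is
disclosed on the report; all three are computed and retained.

Cohort summaries report counts and percentages (100·count/N, rounded half
away from zero to one decimal — the rounding that reproduces published
cohort-table arithmetic such as 393/924 → 42.5%). One published cohort
row is internally inconsistent (any-rare printed as 312/23.6% while its
category counts sum to 309 → 23.6% and the accompanying text says 23.9%);
this package always computes percentages from the category counts it is
given rather than reproducing any printed number.

## Synthetic-data generator

What it emulates, with defaults chosen once to mirror the study
conditions: cohort mix 28.3% FH / 40.1% HTG / 31.6% other; relevant
rare-variant carriage 42.5% (FH) and 23.9% (HTG); biallelic carrier
fractions 3% / 15%; a normolipidemic reference of 503; depth 200× with
negative-binomial dispersion `size=800` (variance 1.25× Poisson — a
moderately overdispersed, well-normalized capture panel) across the
~700 panel targets with log-normal target efficiency (σ = 0.3) and
per-sample library factors (σ = 0.15); default CNV spikes mirroring
recurrent real phenomena (LDLR exon 2–6 het deletion, PCSK9 whole-gene
duplication, GPIHBP1 whole-gene hom deletion); trait-raising allele
enrichment as an odds multiplier (1.1 FH / 1.4 HTG) on the
phenotype-matched trait's SNPs; and an annotation miscall rate (default
2%) that flips all three tool calls and jitters CADD on affected rows.
Lipid values are drawn per phenotype to respect the referral thresholds,
with additive score and carrier effects; the effect sizes are calibrated
constants, not estimates. All randomness flows from one seed;
identical configs produce bit-identical files.

What it does **not** emulate: linkage disequilibrium between score SNPs,
annotator disagreement structure, GC/batch depth artifacts, mosaicism,
population stratification. Recovery tests on this generator therefore
establish algorithmic correctness under the stated generative model —
they do not estimate clinical sensitivity or specificity on real capture
data.

Ground truth (per-sample category, diagnosis, spiked variants/CNVs, raw
scores, extreme flags) is computed by the generator from its own spike
bookkeeping, independently of the pipeline modules. On noise-free cohorts
the full pipeline reproduces truth categories and diagnoses exactly; at
the default annotation noise rate, category recovery stays ≥ 95%.

## Numerical and degenerate-input choices

- Percentile ties: `percentile_of` counts ties as ≤ (empirical CDF);
  `classify_extreme` is ≥-inclusive at the threshold; the two agree
  (extreme ⇔ percentile ≥ 90) including under ties.
- Depth matrices with an all-zero sample column are rejected; all-zero
  target rows are uncallable and bridged or skipped, never called.
- Reference sd of zero at a target makes its z undefined → uncallable.
- Percentage rounding is decimal half-away-from-zero, not banker's.
- Cascade boundaries: MAF = threshold passes; CADD = 20 enters the strict
  tier; CADD = 10 passes relevance.
- Multi-allelic VCF records are split into bi-allelic records on ingestion;
  genotypes are read per alternate allele.
- Problem sizes in the test suite and acceptance script (100-patient
  cohorts, 50 null samples, 40 CNV spikes, n = 10,000 for distributional
  checks) were chosen so the statistical assertions have comfortable
  power while the whole suite runs in seconds.

## Known limitations

- Depth-only CNV calling cannot resolve breakpoints or distinguish
  same-span events; whole-panel or whole-sample copy changes are
  invisible by construction.
- Unphased biallelic determination over-calls when two heterozygous
  variants are in cis.
- The shipped panel coordinates and score weights are synthetic; results
  on them are demonstrations of machinery, not of any real locus.
- The filter cascade's published stage counts (tens of thousands of
  variants down to a few thousand) depend on supplementary variant tables
  that are not redistributable; the cascade is validated here by a
  hand-evaluated fixture and order/monotonicity properties instead.
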