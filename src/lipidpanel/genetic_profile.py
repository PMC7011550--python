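"""Patient-level genetic profiling and cohort summaries.

Synthesizes rare-variant findings (SNVs/indels and CNVs in
phenotype-relevant genes) and the phenotype-matched extreme polygenic-score
flag into a four-way genetic profile: rare variant only, rare variant plus
extreme score, extreme score only, or no relevant genetic determinant.
Gene/zygosity diagnosis rules then map qualifying findings to a clinical
label (e.g. heterozygous LDLR/APOB/PCSK9 in an FH context -> HeFH; biallelic
variants in LPL/APOC2/APOA5/GPIHBP1/LMF1 -> familial chylomicronemia
syndrome).

Biallelic state is determined from unphased genotypes: one homozygous
variant, or two heterozygous variants in the same gene (assumed in trans --
a documented over-call risk), or a homozygous deletion.  Heterozygous CNVs
contribute one allele.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Optional

import pandas as pd

from .cnv_caller import CnvCall
from .errors import ProfileError
from .panel_model import PanelDefinition, phenotype_gene_set
from .prioritization import is_phenotype_relevant
from .variant_io import AnnotatedVariant

PROFILE_CATEGORIES = ("rare_only", "rare_plus_extreme", "extreme_only", "none")
REPORT_CATEGORIES = ("a_diagnosis", "b_confirmation", "c_relevant", "d_negative")

# phenotype thresholds (mmol/L except Lp(a) in mg/dL)
TG_MILD_MIN = 1.8
TG_SEVERE_MIN = 10.0
LDL_HIGH_MIN = 5.0  # strict: LDL must exceed this
LPA_HIGH_MIN = 36.0

CHOL_MMOL_TO_MGDL = 38.67
TG_MMOL_TO_MGDL = 88.57

#: which trait's polygenic score matches each referral phenotype
PHENOTYPE_TRAIT = {
    "FH": "LDL",
    "HoFH": "LDL",
    "familial_combined": "TG",
    "hypobetalipoproteinemia": "LDL",
    "HTG": "TG",
    "severe_HTG": "TG",
    "lipodystrophy": "TG",
    "MODY": "TG",
    "hypoalphalipoproteinemia": "HDL",
    "high_Lpa": "LDL",
}


@dataclass
class LipidProfile:
    """Fasting lipid panel values; None where unmeasured."""

    total_chol: Optional[float] = None  # mmol/L
    ldl_chol: Optional[float] = None  # mmol/L
    hdl_chol: Optional[float] = None  # mmol/L
    triglyceride: Optional[float] = None  # mmol/L
    lpa: Optional[float] = None  # mg/dL
    apob: Optional[float] = None  # g/L
    apoa1: Optional[float] = None  # g/L

    def __post_init__(self):
        for name, value in vars(self).items():
            if value is not None and value < 0:
                raise ProfileError(f"negative lipid value {name}={value}")


@dataclass
class GeneticProfile:
    """Per-sample synthesis of genetic determinants."""

    sample_id: str
    phenotype: str
    relevant_rare_variants: list = field(default_factory=list)
    extreme_score: bool = False
    category: str = "none"
    diagnosis: Optional[str] = None
    report_category: str = "d_negative"


@dataclass(frozen=True)
class DiagnosisRule:
    """One gene-set/zygosity -> diagnosis mapping."""

    gene_set: frozenset
    required_allelic_state: str  # biallelic | heterozygous | either
    diagnosis_label: str
    phenotype_context: Optional[frozenset] = None  # None = any phenotype

    def __post_init__(self):
        if self.required_allelic_state not in ("biallelic", "heterozygous", "either"):
            raise ProfileError(
                f"rule {self.diagnosis_label}: invalid allelic state "
                f"{self.required_allelic_state!r}"
            )


def default_diagnosis_rules(panel: Optional[PanelDefinition] = None) -> list:
    """The shipped ordered rule list; validated against the panel if given."""
    data = resources.files("lipidpanel") / "data" / "diagnosis_rules.json"
    with resources.as_file(data) as path, open(path) as fh:
        raw = json.load(fh)["rules"]
    rules = [
        DiagnosisRule(
            gene_set=frozenset(r["gene_set"]),
            required_allelic_state=r["required_allelic_state"],
            diagnosis_label=r["diagnosis_label"],
            phenotype_context=(
                None if r["phenotype_context"] is None
                else frozenset(r["phenotype_context"])
            ),
        )
        for r in raw
    ]
    if panel is not None:
        for rule in rules:
            unknown = rule.gene_set - panel.gene_symbols
            if unknown:
                raise ProfileError(
                    f"rule {rule.diagnosis_label}: genes not on panel: "
                    f"{sorted(unknown)}"
                )
    return rules


# ---------------------------------------------------------------------------
# phenotype assignment and unit conversion


def assign_phenotype(lp: LipidProfile) -> str:
    """Deterministic precedence-ordered phenotype from lipid values.

    Order: severe hypertriglyceridemia (TG >= 10 mmol/L) > combined
    LDL/TG elevation (familial_combined) > suspected FH (LDL > 5.0, strict)
    > hypertriglyceridemia (TG >= 1.8) > elevated Lp(a) (>= 36 mg/dL) >
    unclassified.  Referral phenotype, when present in the input, overrides
    this computed assignment upstream.
    """
    values = (lp.total_chol, lp.ldl_chol, lp.hdl_chol, lp.triglyceride, lp.lpa)
    if all(v is None for v in values):
        raise ProfileError("cannot assign phenotype: all lipid values missing")
    tg = lp.triglyceride
    ldl = lp.ldl_chol
    if tg is not None and tg >= TG_SEVERE_MIN:
        return "severe_HTG"
    if ldl is not None and ldl > LDL_HIGH_MIN and tg is not None and tg >= TG_MILD_MIN:
        return "familial_combined"
    if ldl is not None and ldl > LDL_HIGH_MIN:
        return "FH"
    if tg is not None and tg >= TG_MILD_MIN:
        return "HTG"
    if lp.lpa is not None and lp.lpa >= LPA_HIGH_MIN:
        return "high_Lpa"
    return "unclassified"


def convert_units(value: float, analyte: str) -> float:
    """mmol/L -> mg/dL: x38.67 for cholesterol, x88.57 for triglyceride."""
    if value < 0:
        raise ProfileError(f"negative value {value}")
    factors = {"cholesterol": CHOL_MMOL_TO_MGDL, "triglyceride": TG_MMOL_TO_MGDL}
    if analyte not in factors:
        raise ProfileError(f"unknown analyte {analyte!r}")
    return value * factors[analyte]


# ---------------------------------------------------------------------------
# profile classification


def classify_profile(rare_findings, extreme: bool) -> str:
    """Four-way category from rare findings and the extreme-score flag."""
    if rare_findings and extreme:
        return "rare_plus_extreme"
    if rare_findings:
        return "rare_only"
    if extreme:
        return "extreme_only"
    return "none"


def _allele_dose(finding) -> int:
    if isinstance(finding, AnnotatedVariant):
        return 2 if finding.zygosity == "homozygous" else 1
    if isinstance(finding, CnvCall):
        return 2 if finding.state == "hom_deletion" else 1
    raise ProfileError(f"unsupported finding type {type(finding).__name__}")


def _finding_gene(finding) -> str:
    return finding.gene


def gene_allelic_states(findings) -> dict:
    """Per-gene allelic state from unphased findings.

    Total allele dose >= 2 in one gene (one hom variant, two het variants,
    a hom deletion, or a het SNV plus a het CNV) -> 'biallelic'; dose 1 ->
    'heterozygous'.  Multiple CNV calls in one gene contribute only the
    largest single-call dose: depth-only calling cannot tell two events in
    trans from one split or tandem event, so they are conservatively treated
    as one allele.
    """
    snv_dose: dict[str, int] = {}
    cnv_dose: dict[str, int] = {}
    for f in findings:
        gene = _finding_gene(f)
        if isinstance(f, CnvCall):
            cnv_dose[gene] = max(cnv_dose.get(gene, 0), _allele_dose(f))
        else:
            snv_dose[gene] = snv_dose.get(gene, 0) + _allele_dose(f)
    dose = {
        g: snv_dose.get(g, 0) + cnv_dose.get(g, 0)
        for g in set(snv_dose) | set(cnv_dose)
    }
    return {g: ("biallelic" if d >= 2 else "heterozygous") for g, d in dose.items()}


def apply_diagnosis_rules(findings, phenotype: str, rules) -> Optional[str]:
    """First matching rule (config order) wins; None when nothing matches."""
    states = gene_allelic_states(findings)
    for rule in rules:
        if rule.phenotype_context is not None and phenotype not in rule.phenotype_context:
            continue
        for gene in rule.gene_set:
            state = states.get(gene)
            if state is None:
                continue
            if (
                rule.required_allelic_state == "either"
                or state == rule.required_allelic_state
            ):
                return rule.diagnosis_label
    return None


def build_profile(
    sample_id: str,
    phenotype: str,
    variants,
    cnv_calls,
    scores: dict,
    panel: PanelDefinition,
    rules,
    prior_diagnosis: bool = False,
) -> GeneticProfile:
    """Assemble one sample's genetic profile.

    ``variants``/``cnv_calls`` are the sample's annotated SNVs/indels and
    CNV calls; ``scores`` maps trait -> PolygenicScoreResult with the
    ``extreme`` flag already set against the reference distribution.  Only
    findings in the phenotype's causal gene set count as relevant; the
    extreme flag is taken from the phenotype-matched trait.
    """
    gene_set = phenotype_gene_set(panel, phenotype)
    relevant: list = [
        v for v in variants if is_phenotype_relevant(v, phenotype, panel)
    ]
    relevant += [c for c in cnv_calls if c.gene in gene_set]

    trait = PHENOTYPE_TRAIT.get(phenotype)
    extreme = False
    if trait is not None and trait in scores and scores[trait].extreme is not None:
        extreme = bool(scores[trait].extreme)

    category = classify_profile(relevant, extreme)
    diagnosis = apply_diagnosis_rules(relevant, phenotype, rules)
    if diagnosis is not None:
        report_category = "b_confirmation" if prior_diagnosis else "a_diagnosis"
    elif category != "none":
        report_category = "c_relevant"
    else:
        report_category = "d_negative"
    return GeneticProfile(
        sample_id=sample_id,
        phenotype=phenotype,
        relevant_rare_variants=relevant,
        extreme_score=extreme,
        category=category,
        diagnosis=diagnosis,
        report_category=report_category,
    )


# ---------------------------------------------------------------------------
# cohort summaries


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round half away from zero (the arithmetic behind printed percentages)."""
    quant = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quant, rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    """Counts and percentages of genetic-determinant categories in a cohort."""

    phenotype: str
    n: int
    counts: dict
    percentages: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "measure": list(self.counts),
                "count": list(self.counts.values()),
                "percent": [self.percentages[k] for k in self.counts],
            }
        )


SUMMARY_MEASURES = (
    "any_rare",
    "any_extreme",
    "rare_only",
    "rare_plus_extreme",
    "extreme_only",
    "none",
)


def summarize_cohort(profiles, phenotype: str) -> CohortSummary:
    """Category counts and percentages for one phenotype cohort.

    Percentages are 100 x count / N, rounded half away from zero to one
    decimal.  any_rare = rare_only + rare_plus_extreme; any_extreme =
    extreme_only + rare_plus_extreme.
    """
    profiles = list(profiles)
    if not profiles:
        raise ProfileError("empty cohort")
    for p in profiles:
        if p.phenotype != phenotype:
            raise ProfileError(
                f"profile {p.sample_id} has phenotype {p.phenotype}, "
                f"expected {phenotype}"
            )
    n = len(profiles)
    cat_counts = {c: sum(1 for p in profiles if p.category == c) for c in PROFILE_CATEGORIES}
    counts = {
        "any_rare": cat_counts["rare_only"] + cat_counts["rare_plus_extreme"],
        "any_extreme": cat_counts["extreme_only"] + cat_counts["rare_plus_extreme"],
        **cat_counts,
    }
    percentages = {k: round_half_away(100.0 * v / n, 1) for k, v in counts.items()}
    return CohortSummary(phenotype=phenotype, n=n, counts=counts, percentages=percentages)


def profiles_from_counts(
    phenotype: str,
    rare_only: int,
    rare_plus_extreme: int,
    extreme_only: int,
    none: int,
) -> list:
    """Expand printed category counts into minimal profiles (for arithmetic
    on published cohort tables, where patient-level data is unavailable)."""
    profiles = []
    spec = (
        ("rare_only", rare_only, ["x"], False),
        ("rare_plus_extreme", rare_plus_extreme, ["x"], True),
        ("extreme_only", extreme_only, [], True),
        ("none", none, [], False),
    )
    i = 0
    for category, count, findings, extreme in spec:
        for _ in range(count):
            i += 1
            profiles.append(
                GeneticProfile(
                    sample_id=f"{phenotype}_{i:04d}",
                    phenotype=phenotype,
                    relevant_rare_variants=list(findings),
                    extreme_score=extreme,
                    category=category,
                )
            )
    return profiles
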