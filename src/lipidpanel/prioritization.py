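"""Rare-variant prioritization: the filter cascade and relevance rules.

The cascade keeps variants that are (1) rare -- population MAF <= 1% or
absent from databases; (2) protein-altering -- consequence ontologies that
change the amino-acid sequence or canonical splice sites; and (3) predicted
deleterious -- flagged damaging by at least one of SIFT, PolyPhen2 or
MutationTaster, or carrying a loss-of-function ontology outright.  Stage
counts are reported as unique variants (cross-sample deduplication), with
two subsets of the final stage: LOF-ontology variants and those at the
stricter CADD PHRED >= 20 tier.

LOF ontologies (frameshift, splice acceptor/donor, stop gain, stop loss)
bypass the missense-oriented prediction tools, which do not score truncating
variants.  In-frame indels count as protein-altering but not LOF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .panel_model import PanelDefinition, phenotype_gene_set
from .variant_io import AnnotatedVariant, unique_variants

PROTEIN_ALTERING = frozenset(
    {
        "missense",
        "stop_gain",
        "stop_loss",
        "frameshift",
        "inframe_indel",
        "splice_acceptor",
        "splice_donor",
    }
)
LOF_ONTOLOGIES = frozenset(
    {"frameshift", "splice_acceptor", "splice_donor", "stop_gain", "stop_loss"}
)

CASCADE_STAGES = ("total", "rare", "protein_altering", "predicted_deleterious")

DEFAULT_MAF_THRESHOLD = 0.01
DEFAULT_CADD_STRICT = 20.0
RELEVANCE_CADD_MIN = 10.0


def is_rare(v: AnnotatedVariant, maf_threshold: float = DEFAULT_MAF_THRESHOLD) -> bool:
    """True iff MAF absent from databases or <= threshold (boundary passes)."""
    return v.population_maf is None or v.population_maf <= maf_threshold


def is_protein_altering(v: AnnotatedVariant) -> bool:
    """True iff the consequence changes the protein or a canonical splice site."""
    return v.consequence in PROTEIN_ALTERING


def is_lof(v: AnnotatedVariant) -> bool:
    """True iff the consequence is a loss-of-function ontology."""
    return v.consequence in LOF_ONTOLOGIES


def _n_damaging(v: AnnotatedVariant) -> int:
    return (
        (v.sift == "deleterious")
        + (v.polyphen2 == "damaging")
        + (v.mutation_taster == "disease_causing")
    )


def is_predicted_deleterious(v: AnnotatedVariant, policy: str = "any_tool") -> bool:
    """Prediction-tool verdict, with LOF ontologies bypassing the tools.

    ``any_tool`` (default): one damaging call suffices.  ``all_tools``: all
    three tools must call damaging (an ``unknown`` call fails the
    conjunction); intended for sensitivity analysis.
    """
    if policy not in ("any_tool", "all_tools"):
        raise ValueError(f"unknown policy {policy!r}")
    if is_lof(v):
        return True
    if policy == "any_tool":
        return _n_damaging(v) >= 1
    return _n_damaging(v) == 3


@dataclass
class CascadeResult:
    """Output of the progressive filter cascade.

    ``stage_counts`` maps stage name -> unique-variant count, in cascade
    order, plus the ``lof`` and ``cadd_strict`` subsets of the final stage.
    ``surviving`` maps stage name -> the sample-level records still in play.
    """

    stage_counts: dict = field(default_factory=dict)
    surviving: dict = field(default_factory=dict)
    maf_threshold: float = DEFAULT_MAF_THRESHOLD
    cadd_strict: float = DEFAULT_CADD_STRICT
    policy: str = "any_tool"


def run_cascade(
    records,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    cadd_strict: float = DEFAULT_CADD_STRICT,
    policy: str = "any_tool",
) -> CascadeResult:
    """Apply the cascade rare -> protein-altering -> predicted-deleterious.

    Counts at every stage are unique variants; the LOF and CADD-strict
    subsets are taken from the final stage's survivors (CADD == threshold is
    included in the strict tier).
    """
    result = CascadeResult(
        maf_threshold=maf_threshold, cadd_strict=cadd_strict, policy=policy
    )
    stages = [
        ("total", lambda v: True),
        ("rare", lambda v: is_rare(v, maf_threshold)),
        ("protein_altering", is_protein_altering),
        ("predicted_deleterious", lambda v: is_predicted_deleterious(v, policy)),
    ]
    current = list(records)
    for name, predicate in stages:
        current = [v for v in current if predicate(v)]
        result.surviving[name] = current
        result.stage_counts[name] = len(unique_variants(current))
    lof = [v for v in current if is_lof(v)]
    strict = [v for v in current if v.cadd_phred >= cadd_strict]
    result.surviving["lof"] = lof
    result.surviving["cadd_strict"] = strict
    result.stage_counts["lof"] = len(unique_variants(lof))
    result.stage_counts["cadd_strict"] = len(unique_variants(strict))
    return result


def is_phenotype_relevant(
    v: AnnotatedVariant,
    phenotype: str,
    panel: PanelDefinition,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    cadd_min: float = RELEVANCE_CADD_MIN,
) -> bool:
    """Does this variant count as a relevant finding for the phenotype?

    Requires all of: gene in the phenotype's causal gene set; rare;
    protein-altering; CADD PHRED >= 10 (boundary passes); and at least one
    damaging tool call or a LOF ontology.
    """
    gene_set = phenotype_gene_set(panel, phenotype)  # raises on unknown key
    return (
        v.gene in gene_set
        and is_rare(v, maf_threshold)
        and is_protein_altering(v)
        and v.cadd_phred >= cadd_min
        and (_n_damaging(v) >= 1 or is_lof(v))
    )
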