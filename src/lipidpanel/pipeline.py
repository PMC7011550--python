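"""End-to-end composition: files in, per-patient genetic profiles out.

Thin orchestration over the other modules: read annotated variants, call
CNVs per patient against the depth-matrix reference samples, compute and
classify all three polygenic scores, then build profiles using each
patient's referral phenotype (falling back to lipid-derived assignment when
no referral is given).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cnv_caller import CallerParams, DepthMatrix, call_cnvs
from .genetic_profile import (
    LipidProfile,
    assign_phenotype,
    build_profile,
    default_diagnosis_rules,
)
from .panel_model import TRAITS, PanelDefinition
from .polygenic_score import (
    ReferenceDistribution,
    genotype_vectors_from_vcf,
    score_and_classify,
)
from .variant_io import read_annotated_variants, records_by_sample


@dataclass
class CohortResult:
    profiles: dict = field(default_factory=dict)  # sample_id -> GeneticProfile
    scores: dict = field(default_factory=dict)  # sample_id -> {trait: result}
    cnv_calls: dict = field(default_factory=dict)  # sample_id -> [CnvCall]


def characterize_cohort(
    panel: PanelDefinition,
    vcf_path,
    annotation_path,
    depth_path,
    lipid_path,
    references: dict,
    rules=None,
    caller_params: CallerParams = None,
    depth_reference_ids=None,
) -> CohortResult:
    """Run the full analytic pathway for a cohort.

    ``references`` maps trait -> ReferenceDistribution for extreme-score
    classification.  ``depth_reference_ids`` names the CNV-free reference
    columns of the depth matrix; by default, samples absent from the lipid
    table are treated as reference samples.
    """
    rules = rules if rules is not None else default_diagnosis_rules(panel)
    lipids = pd.read_csv(lipid_path, sep="\t")
    by_sample = records_by_sample(read_annotated_variants(vcf_path, annotation_path))

    depth = DepthMatrix.from_tsv(depth_path)
    patient_ids = list(lipids["sample_id"].astype(str))
    if depth_reference_ids is None:
        depth_reference_ids = [s for s in depth.samples if s not in set(patient_ids)]

    score_vectors = {
        trait: genotype_vectors_from_vcf(vcf_path, panel.score_snps, trait)
        for trait in TRAITS
    }

    result = CohortResult()
    for row in lipids.itertuples(index=False):
        sid = str(row.sample_id)
        referral = getattr(row, "referral_phenotype", None)
        if referral is None or (isinstance(referral, float) and pd.isna(referral)):
            lp = LipidProfile(
                total_chol=getattr(row, "total_chol", None),
                ldl_chol=getattr(row, "ldl_chol", None),
                hdl_chol=getattr(row, "hdl_chol", None),
                triglyceride=getattr(row, "triglyceride", None),
                lpa=getattr(row, "lpa", None),
            )
            phenotype = assign_phenotype(lp)
        else:
            phenotype = str(referral)

        scores = {}
        for trait in TRAITS:
            vec = score_vectors[trait].get(sid)
            if vec is not None:
                scores[trait] = score_and_classify(
                    vec, panel.score_snps_for(trait), references.get(trait)
                )
        calls = (
            call_cnvs(depth, sid, depth_reference_ids, caller_params)
            if sid in depth.samples
            else []
        )
        result.scores[sid] = scores
        result.cnv_calls[sid] = calls
        result.profiles[sid] = build_profile(
            sample_id=sid,
            phenotype=phenotype,
            variants=by_sample.get(sid, []),
            cnv_calls=calls,
            scores=scores,
            panel=panel,
            rules=rules,
        )
    return result


def load_references(score_paths: dict) -> dict:
    """trait -> ReferenceDistribution from one-column score TSVs."""
    return {
        trait: ReferenceDistribution.from_tsv(trait, path)
        for trait, path in score_paths.items()
    }
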