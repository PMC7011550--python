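"""Per-patient report rendering (JSON and plain text).

Disclosure follows clinic practice: all three trait scores are computed and
stored, but only the score matching the referral phenotype appears on the
patient's report.  The weighted score is presented alongside a simple tally
of trait-raising alleles, which patients tend to find easier to grasp than a
weighted statistic.  Report outcomes fall into four categories: (a) a
genetically based diagnosis, (b) genetic confirmation of a prior clinical
diagnosis, (c) a relevant (not confirmed-causal) genetic result, or (d) a
negative result.

Rendering is deterministic: the same profile renders to byte-identical
output.
"""

from __future__ import annotations

import json
from importlib import resources

from .cnv_caller import CnvCall
from .errors import ProfileError
from .genetic_profile import PHENOTYPE_TRAIT, GeneticProfile
from .prioritization import is_lof
from .variant_io import AnnotatedVariant

_CATEGORY_TEXT = {
    "a_diagnosis": "A genetically based diagnosis",
    "b_confirmation": "Genetic confirmation of the prior clinical diagnosis",
    "c_relevant": "A relevant genetic result",
    "d_negative": (
        "A negative result: we were unable to identify any sort of genetic "
        "determinant related to the phenotype"
    ),
}


def _finding_dict(finding) -> dict:
    if isinstance(finding, AnnotatedVariant):
        tier = "loss_of_function" if is_lof(finding) else "predicted_damaging"
        return {
            "gene": finding.gene,
            "description": (
                f"{finding.chromosome}:{finding.position} "
                f"{finding.ref_allele}>{finding.alt_allele} ({finding.consequence})"
            ),
            "zygosity": finding.zygosity,
            "tier": tier,
        }
    if isinstance(finding, CnvCall):
        zygosity = {
            "het_deletion": "heterozygous",
            "hom_deletion": "homozygous",
            "duplication": "heterozygous",
        }[finding.state]
        return {
            "gene": finding.gene,
            "description": f"{finding.kind} of {finding.region}",
            "zygosity": zygosity,
            "tier": "copy_number_variant",
        }
    raise ProfileError(f"unsupported finding type {type(finding).__name__}")


def report_dict(profile: GeneticProfile, scores: dict) -> dict:
    """Machine-readable report document for one patient.

    ``scores`` maps trait -> PolygenicScoreResult for all computed traits;
    only the phenotype-matched one is disclosed.  A phenotype with a mapped
    trait but no computed score raises.
    """
    trait = PHENOTYPE_TRAIT.get(profile.phenotype)
    disclosed = None
    if trait is not None:
        if trait not in scores:
            raise ProfileError(
                f"missing {trait} score for referral phenotype {profile.phenotype}"
            )
        s = scores[trait]
        disclosed = {
            "trait": trait,
            "weighted_score": round(float(s.raw_score), 6),
            "allele_tally": int(s.allele_tally),
            "n_snps_used": int(s.n_snps_used),
            "percentile": None if s.percentile is None else round(float(s.percentile), 2),
            "extreme": s.extreme,
        }
    return {
        "sample_id": profile.sample_id,
        "referral_phenotype": profile.phenotype,
        "report_category": profile.report_category,
        "diagnosis": profile.diagnosis,
        "rare_variant_findings": [
            _finding_dict(f) for f in profile.relevant_rare_variants
        ],
        "disclosed_score": disclosed,
        "notes": _CATEGORY_TEXT[profile.report_category],
    }


def render_report(profile: GeneticProfile, scores: dict, format: str = "json") -> str:
    """Render a report as 'json' or 'text'; deterministic output."""
    doc = report_dict(profile, scores)
    validate_report(doc)
    if format == "json":
        return json.dumps(doc, indent=2, sort_keys=True) + "\n"
    if format != "text":
        raise ValueError(f"unknown report format {format!r}")
    lines = [
        f"GENETIC REPORT — sample {doc['sample_id']}",
        f"Referral phenotype: {doc['referral_phenotype']}",
        f"Outcome: {_CATEGORY_TEXT[doc['report_category']]}",
    ]
    if doc["diagnosis"]:
        lines.append(f"Diagnosis: {doc['diagnosis']}")
    lines.append("")
    if doc["rare_variant_findings"]:
        lines.append("Rare variant findings:")
        for f in doc["rare_variant_findings"]:
            lines.append(
                f"  - {f['gene']}: {f['description']}, {f['zygosity']} [{f['tier']}]"
            )
    else:
        lines.append("Rare variant findings: none")
    lines.append("")
    if doc["disclosed_score"] is not None:
        s = doc["disclosed_score"]
        pct = "n/a" if s["percentile"] is None else f"{s['percentile']:.1f}"
        extreme = {True: "EXTREME (>= 90th percentile)", False: "not extreme", None: "n/a"}
        lines.append(f"Polygenic score ({s['trait']}):")
        lines.append(
            f"  weighted score {s['weighted_score']:.4f} over {s['n_snps_used']} SNPs"
        )
        lines.append(f"  trait-raising allele tally: {s['allele_tally']}")
        lines.append(f"  reference percentile: {pct} — {extreme[s['extreme']]}")
    else:
        lines.append("Polygenic score: no score matches the referral phenotype")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# schema check (structural: required keys, types, enums)


def _load_schema() -> dict:
    data = resources.files("lipidpanel") / "data" / "report_schema.json"
    with resources.as_file(data) as path, open(path) as fh:
        return json.load(fh)


_TYPE_MAP = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "integer": int,
    "boolean": bool,
    "null": type(None),
}


def _check(obj, schema, where: str):
    types = schema.get("type")
    if types is not None:
        if isinstance(types, str):
            types = [types]
        allowed = tuple(t for name in types for t in (
            _TYPE_MAP[name] if isinstance(_TYPE_MAP[name], tuple) else (_TYPE_MAP[name],)
        ))
        if not isinstance(obj, allowed) or (
            isinstance(obj, bool) and "boolean" not in types
        ):
            raise ProfileError(f"report schema violation at {where}: type {types}")
    if "enum" in schema and obj not in schema["enum"]:
        raise ProfileError(f"report schema violation at {where}: {obj!r} not in enum")
    if isinstance(obj, dict):
        for key in schema.get("required", []):
            if key not in obj:
                raise ProfileError(f"report schema violation at {where}: missing {key}")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                _check(obj[key], sub, f"{where}.{key}")
    if isinstance(obj, list) and "items" in schema:
        for i, item in enumerate(obj):
            _check(item, schema["items"], f"{where}[{i}]")


def validate_report(doc: dict) -> None:
    """Structurally validate a report dict against the shipped schema."""
    _check(doc, _load_schema(), "report")
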