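"""Small weighted polygenic lipid scores and extreme-score classification.

For each trait (LDL cholesterol, triglyceride, HDL cholesterol) the score is
the sum over the trait's score SNPs of the trait-raising allele count
(0, 1 or 2) times that allele's GWAS beta weight.  A score is "extreme" when
it is greater than or equal to the 90th percentile of a normolipidemic
reference distribution; percentiles are empirical nearest-rank (inclusive at
the threshold, no interpolation), so the threshold is always a realized
reference value.

Missing genotypes contribute 0 to the sum; ``n_snps_used`` records how many
loci actually entered, so low-coverage scores can be flagged downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from .errors import ScoreError
from .panel_model import TRAITS


@dataclass
class GenotypeVector:
    """Trait-raising allele counts for one sample at one trait's score SNPs."""

    sample_id: str
    trait: str
    counts: dict  # snp_id -> 0|1|2 or None (missing)

    def __post_init__(self):
        if self.trait not in TRAITS:
            raise ScoreError(f"unknown trait {self.trait!r}")
        for snp_id, g in self.counts.items():
            if g is not None and g not in (0, 1, 2):
                raise ScoreError(
                    f"{self.sample_id}/{snp_id}: allele count {g!r} not in {{0,1,2}}"
                )


@dataclass
class PolygenicScoreResult:
    sample_id: str
    trait: str
    raw_score: float
    n_snps_used: int
    allele_tally: int
    percentile: Optional[float] = None
    extreme: Optional[bool] = None


@dataclass
class ReferenceDistribution:
    """Raw scores of a normolipidemic reference cohort for one trait."""

    trait: str
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.sort(np.asarray(self.scores, dtype=float))
        if self.scores.size == 0:
            raise ScoreError("empty reference distribution")
        if self.scores.size < 10:
            raise ScoreError(
                f"reference too small for percentile estimation "
                f"(n={self.scores.size} < 10)"
            )

    @property
    def n(self) -> int:
        return int(self.scores.size)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"score": self.scores}).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, trait, path) -> "ReferenceDistribution":
        frame = pd.read_csv(path, sep="\t")
        return cls(trait=trait, scores=frame["score"].to_numpy(dtype=float))


def _check_vector(g: GenotypeVector, snps) -> list:
    snps = [s for s in snps]
    by_id = {s.snp_id: s for s in snps}
    for snp_id in g.counts:
        snp = by_id.get(snp_id)
        if snp is None:
            raise ScoreError(f"{g.sample_id}: count for unknown score SNP {snp_id!r}")
        if snp.trait != g.trait:
            raise ScoreError(
                f"{g.sample_id}: SNP {snp_id} belongs to {snp.trait} score, "
                f"not {g.trait}"
            )
    return snps


def compute_score(g: GenotypeVector, snps) -> PolygenicScoreResult:
    """Weighted score: sum of count x beta over non-missing loci."""
    snps = _check_vector(g, snps)
    raw = 0.0
    tally = 0
    used = 0
    for snp in snps:
        count = g.counts.get(snp.snp_id)
        if count is None:
            continue
        raw += count * snp.beta
        tally += count
        used += 1
    return PolygenicScoreResult(
        sample_id=g.sample_id,
        trait=g.trait,
        raw_score=raw,
        n_snps_used=used,
        allele_tally=tally,
    )


def allele_tally(g: GenotypeVector) -> int:
    """Unweighted trait-raising allele count (for patient-facing reports)."""
    return sum(c for c in g.counts.values() if c is not None)


def percentile_of(score: float, ref: ReferenceDistribution) -> float:
    """Empirical-CDF percentile: 100 x #(reference <= score) / n."""
    return 100.0 * float(np.searchsorted(ref.scores, score, side="right")) / ref.n


def extreme_threshold(ref: ReferenceDistribution, q: float = 90.0) -> float:
    """Nearest-rank q-th percentile: the ceil(qn/100)-th order statistic."""
    rank = math.ceil(q / 100.0 * ref.n)  # 1-based
    return float(ref.scores[max(rank, 1) - 1])


def classify_extreme(score: float, ref: ReferenceDistribution, q: float = 90.0) -> bool:
    """True iff score >= the reference's nearest-rank q-th percentile."""
    return bool(score >= extreme_threshold(ref, q))


def score_and_classify(
    g: GenotypeVector, snps, ref: Optional[ReferenceDistribution]
) -> PolygenicScoreResult:
    """Compute the score and, when a reference is given, its percentile/flag."""
    result = compute_score(g, snps)
    if ref is not None:
        if ref.trait != g.trait:
            raise ScoreError(f"reference trait {ref.trait} != vector trait {g.trait}")
        result.percentile = percentile_of(result.raw_score, ref)
        result.extreme = classify_extreme(result.raw_score, ref)
    return result


# ---------------------------------------------------------------------------
# genotype extraction from VCF


def genotype_vectors_from_vcf(vcf_path, snps, trait: str) -> dict:
    """Extract trait-raising allele counts for one trait from a VCF.

    Score SNPs are matched by VCF ID; counts are oriented to the
    trait-raising allele regardless of which of ref/alt it is.  Sites absent
    from the VCF (or with missing genotypes) are recorded as missing.
    Returns {sample_id: GenotypeVector}.
    """
    trait_snps = {s.snp_id: s for s in snps if s.trait == trait}
    counts: dict[str, dict] = {}
    with pysam.VariantFile(str(vcf_path)) as vcf:
        sample_ids = list(vcf.header.samples)
        for sid in sample_ids:
            counts[sid] = {snp_id: None for snp_id in trait_snps}
        for rec in vcf:
            snp = trait_snps.get(rec.id)
            if snp is None:
                continue
            alleles = (rec.ref,) + tuple(rec.alts or ())
            if snp.raising_allele not in alleles:
                # raising allele unobserved here: every called genotype is 0
                raising_index = None
            else:
                raising_index = alleles.index(snp.raising_allele)
            for sample in rec.samples.values():
                gt = sample.get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                if raising_index is None:
                    counts[sample.name][rec.id] = 0
                else:
                    counts[sample.name][rec.id] = sum(
                        1 for a in gt if a == raising_index
                    )
    return {
        sid: GenotypeVector(sample_id=sid, trait=trait, counts=c)
        for sid, c in counts.items()
    }
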