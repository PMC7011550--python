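"""Reading and writing sample-level annotated small variants.

Genotypes come from VCF; in-silico annotations (gene, consequence ontology,
population MAF, CADD PHRED, SIFT/PolyPhen2/MutationTaster calls) travel in a
sidecar TSV keyed by (chrom, pos, ref, alt).  Keeping annotations out of VCF
INFO isolates the pipeline from the encoding dialects of external annotators.

A MAF absent from population databases is a distinct marker (``None`` in
memory, ``NA`` on disk), never 0.0: downstream rarity filtering treats
"absent" as rare by definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd
import pysam

from .errors import VariantInputError

CONSEQUENCES = (
    "missense",
    "stop_gain",
    "stop_loss",
    "frameshift",
    "inframe_indel",
    "splice_acceptor",
    "splice_donor",
    "synonymous",
    "other",
)
SIFT_CALLS = ("deleterious", "tolerated", "unknown")
POLYPHEN2_CALLS = ("damaging", "benign", "unknown")
MUTATION_TASTER_CALLS = ("disease_causing", "polymorphism", "unknown")

ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "maf",
    "cadd_phred",
    "sift",
    "polyphen2",
    "mutation_taster",
]


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a variant across samples: (chrom, pos, ref, alt)."""

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str


@dataclass
class AnnotatedVariant:
    """One sample-level small variant with genotype and annotations."""

    sample_id: str
    gene: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    zygosity: str  # heterozygous | homozygous
    consequence: str
    population_maf: Optional[float]  # None = absent from population databases
    cadd_phred: float
    sift: str = "unknown"
    polyphen2: str = "unknown"
    mutation_taster: str = "unknown"

    def __post_init__(self):
        if self.position < 1:
            raise VariantInputError(
                f"{self.sample_id}: position must be >= 1, got {self.position}"
            )
        if self.zygosity not in ("heterozygous", "homozygous"):
            raise VariantInputError(f"invalid zygosity {self.zygosity!r}")
        if self.consequence not in CONSEQUENCES:
            raise VariantInputError(
                f"consequence {self.consequence!r} not in closed vocabulary"
            )
        if self.population_maf is not None and not 0.0 <= self.population_maf <= 1.0:
            raise VariantInputError(
                f"population MAF {self.population_maf} outside [0, 1]"
            )
        if self.cadd_phred < 0:
            raise VariantInputError(f"negative CADD PHRED {self.cadd_phred}")
        if self.sift not in SIFT_CALLS:
            raise VariantInputError(f"invalid SIFT call {self.sift!r}")
        if self.polyphen2 not in POLYPHEN2_CALLS:
            raise VariantInputError(f"invalid PolyPhen2 call {self.polyphen2!r}")
        if self.mutation_taster not in MUTATION_TASTER_CALLS:
            raise VariantInputError(
                f"invalid MutationTaster call {self.mutation_taster!r}"
            )

    @property
    def key(self) -> VariantKey:
        return VariantKey(
            self.chromosome, self.position, self.ref_allele, self.alt_allele
        )


def read_annotation_table(path) -> pd.DataFrame:
    """Read an annotation TSV; ``maf`` column 'NA' becomes missing."""
    table = pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str, "gene": str},
        na_values=["NA"], keep_default_na=False,
    )
    missing = set(ANNOTATION_COLUMNS) - set(table.columns)
    if missing:
        raise VariantInputError(f"{path}: missing annotation columns {sorted(missing)}")
    return table


def write_annotation_table(table: pd.DataFrame, path) -> None:
    """Write an annotation table; missing MAF serialized as 'NA'.

    Column order is normalized so that a read/write cycle reproduces the
    file row-for-row.
    """
    table = table[ANNOTATION_COLUMNS]
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def _annotation_lookup(table: pd.DataFrame) -> dict:
    lookup = {}
    for row in table.itertuples(index=False):
        key = VariantKey(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        lookup[key] = row
    return lookup


def read_annotated_variants(
    vcf_path, annotation_path, *, on_missing_annotation: str = "error"
) -> list[AnnotatedVariant]:
    """Join VCF genotypes with the sidecar annotation table.

    One record is emitted per carrier sample per (bi-allelified) variant:
    genotype 0/1 maps to heterozygous, 1/1 to homozygous, 0/0 and ./. emit
    nothing.  Multi-allelic VCF records are split into bi-allelic records
    before the join.

    ``on_missing_annotation`` controls what happens when a carried VCF
    variant has no annotation row: ``"error"`` raises; ``"unknown"`` emits a
    record with unknown predictions, empty gene, and consequence ``other``.
    """
    if on_missing_annotation not in ("error", "unknown"):
        raise ValueError("on_missing_annotation must be 'error' or 'unknown'")
    lookup = _annotation_lookup(read_annotation_table(annotation_path))
    records: list[AnnotatedVariant] = []
    try:
        vcf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise VariantInputError(f"cannot parse VCF {vcf_path}: {exc}") from exc
    with vcf:
        for rec in vcf:
            if not rec.alts:
                continue
            for alt_index, alt in enumerate(rec.alts, start=1):
                key = VariantKey(rec.chrom, rec.pos, rec.ref, alt)
                ann = lookup.get(key)
                for sample in rec.samples.values():
                    gt = sample.get("GT")
                    if gt is None:
                        continue
                    dose = sum(1 for allele in gt if allele == alt_index)
                    if dose == 0:
                        continue
                    zygosity = "heterozygous" if dose == 1 else "homozygous"
                    if ann is None:
                        if on_missing_annotation == "error":
                            raise VariantInputError(
                                f"no annotation for variant {rec.chrom}:{rec.pos} "
                                f"{rec.ref}>{alt}"
                            )
                        records.append(
                            AnnotatedVariant(
                                sample_id=sample.name,
                                gene="",
                                chromosome=rec.chrom,
                                position=rec.pos,
                                ref_allele=rec.ref,
                                alt_allele=alt,
                                zygosity=zygosity,
                                consequence="other",
                                population_maf=None,
                                cadd_phred=0.0,
                            )
                        )
                        continue
                    maf = None if pd.isna(ann.maf) else float(ann.maf)
                    records.append(
                        AnnotatedVariant(
                            sample_id=sample.name,
                            gene=str(ann.gene),
                            chromosome=rec.chrom,
                            position=rec.pos,
                            ref_allele=rec.ref,
                            alt_allele=alt,
                            zygosity=zygosity,
                            consequence=str(ann.consequence),
                            population_maf=maf,
                            cadd_phred=float(ann.cadd_phred),
                            sift=str(ann.sift),
                            polyphen2=str(ann.polyphen2),
                            mutation_taster=str(ann.mutation_taster),
                        )
                    )
    return records


def unique_variants(records) -> set:
    """Distinct variant keys across samples (recurrence collapses to one)."""
    return {r.key for r in records}


def records_by_sample(records) -> dict:
    """Group annotated variant records per sample id."""
    out: dict[str, list] = {}
    for r in records:
        out.setdefault(r.sample_id, []).append(r)
    return out
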