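"""Panel definition: targeted genes, score SNPs, and phenotype-to-gene lookups.

The panel targets genes in four categories -- causative genes for monogenic
dyslipidemias, inherited lipodystrophies, MODY/inherited diabetes, and
candidate lipoprotein-metabolism genes -- plus a set of GWAS lipid SNPs used
to build small weighted polygenic scores for LDL cholesterol, triglyceride,
and HDL cholesterol.

The default configuration shipped with the package carries 69 genes
(25/16/13/15 across the four categories) and 35 score SNPs (10 LDL, 16 TG,
9 HDL).  Gene coordinates, exon structure, and score-SNP identities/weights
in the shipped config are synthetic placeholders: real per-SNP weights come
from GWAS summary statistics that are external to this package, and the
calling code treats them as ordinary config data.

Coordinates are 1-based inclusive internally; BED export converts to 0-based
half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import PanelConfigError, UnknownPhenotypeError

GENE_CATEGORIES = (
    "monogenic_dyslipidemia",
    "lipodystrophy",
    "mody_diabetes",
    "candidate",
)
INHERITANCE_MODES = ("dominant", "recessive", "either")
TRAITS = ("LDL", "TG", "HDL")

_BASES = {"A", "C", "G", "T"}


def merge_intervals(intervals):
    """Merge overlapping or book-ended 1-based inclusive intervals.

    Returns a sorted tuple of disjoint (start, end) pairs.
    """
    ivs = sorted(tuple(iv) for iv in intervals)
    merged: list[list[int]] = []
    for start, end in ivs:
        if start > end:
            raise PanelConfigError(f"interval start {start} > end {end}")
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((s, e) for s, e in merged)


@dataclass(frozen=True)
class GeneTarget:
    """One targeted gene: its category, intervals and phenotype links."""

    symbol: str
    category: str
    chromosome: str
    intervals: tuple  # ((start, end), ...) 1-based inclusive, merged & sorted
    phenotypes: frozenset = frozenset()
    inheritance: str = "either"

    def __post_init__(self):
        if not self.symbol:
            raise PanelConfigError("gene symbol must be non-empty")
        if self.category not in GENE_CATEGORIES:
            raise PanelConfigError(
                f"gene {self.symbol}: category {self.category!r} not one of "
                f"{GENE_CATEGORIES}"
            )
        if self.inheritance not in INHERITANCE_MODES:
            raise PanelConfigError(
                f"gene {self.symbol}: inheritance {self.inheritance!r} invalid"
            )
        if not self.intervals:
            raise PanelConfigError(f"gene {self.symbol}: no target intervals")
        object.__setattr__(self, "intervals", merge_intervals(self.intervals))
        object.__setattr__(self, "phenotypes", frozenset(self.phenotypes))

    @property
    def span_bp(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)

    def target_labels(self) -> list[str]:
        """Deterministic labels for the gene's targets, in genomic order.

        By convention the first and last intervals of a gene with three or
        more targets are its 5'UTR and 3'UTR; everything between is an exon.
        """
        n = len(self.intervals)
        if n <= 2:
            return [f"Exon {i + 1}" for i in range(n)]
        return ["5'UTR"] + [f"Exon {i}" for i in range(1, n - 1)] + ["3'UTR"]


@dataclass(frozen=True)
class ScoreSNP:
    """One score SNP: trait, trait-raising allele, GWAS weight, frequency.

    ``beta`` is the per-allele effect in trait units, oriented so the
    trait-raising allele has positive weight.  ``raising_allele_freq`` is the
    population frequency of the trait-raising allele (used for HWE
    simulation of reference cohorts).
    """

    snp_id: str
    trait: str
    raising_allele: str
    other_allele: str
    beta: float
    raising_allele_freq: float
    chromosome: str = ""
    position: int = 0

    def __post_init__(self):
        if self.trait not in TRAITS:
            raise PanelConfigError(
                f"score SNP {self.snp_id}: trait {self.trait!r} not in {TRAITS}"
            )
        if self.raising_allele not in _BASES or self.other_allele not in _BASES:
            raise PanelConfigError(f"score SNP {self.snp_id}: invalid allele")
        if self.raising_allele == self.other_allele:
            raise PanelConfigError(f"score SNP {self.snp_id}: identical alleles")
        if not self.beta > 0:
            raise PanelConfigError(
                f"score SNP {self.snp_id}: beta must be > 0 when oriented to "
                f"the trait-raising allele (got {self.beta})"
            )
        if not 0 < self.raising_allele_freq < 1:
            raise PanelConfigError(
                f"score SNP {self.snp_id}: allele frequency must be in (0, 1)"
            )


@dataclass
class PanelDefinition:
    """The full panel: gene targets plus score-SNP definitions."""

    genes: list = field(default_factory=list)
    score_snps: list = field(default_factory=list)
    micro_seq_snp_count: int = 0

    def __post_init__(self):
        if not self.genes:
            raise PanelConfigError("panel must define at least one gene")
        seen = set()
        for g in self.genes:
            if g.symbol in seen:
                raise PanelConfigError(f"duplicate gene symbol {g.symbol!r}")
            seen.add(g.symbol)
        for trait in TRAITS:
            ids = [s.snp_id for s in self.score_snps if s.trait == trait]
            if len(ids) != len(set(ids)):
                raise PanelConfigError(f"duplicate score-SNP id in {trait} score")
        if self.micro_seq_snp_count == 0:
            self.micro_seq_snp_count = len(self.score_snps)

    def gene(self, symbol: str) -> GeneTarget:
        for g in self.genes:
            if g.symbol == symbol:
                return g
        raise PanelConfigError(f"gene {symbol!r} not on panel")

    @property
    def gene_symbols(self) -> set:
        return {g.symbol for g in self.genes}

    def category_counts(self) -> dict:
        counts = {c: 0 for c in GENE_CATEGORIES}
        for g in self.genes:
            counts[g.category] += 1
        return counts

    def score_snps_for(self, trait: str) -> list:
        if trait not in TRAITS:
            raise PanelConfigError(f"unknown trait {trait!r}")
        return [s for s in self.score_snps if s.trait == trait]

    @property
    def phenotype_keys(self) -> set:
        keys = set()
        for g in self.genes:
            keys |= g.phenotypes
        # 'unclassified' is always a legal referral phenotype; it maps to the
        # empty gene set (no relevant monogenic genes).
        keys.add("unclassified")
        return keys


# ---------------------------------------------------------------------------
# phenotype lookups


def phenotype_gene_set(panel: PanelDefinition, phenotype: str) -> set:
    """Causal/relevant gene symbols for a referral phenotype.

    E.g. FH maps to {LDLR, APOB, PCSK9} and hypertriglyceridemia to
    {LPL, APOA5, LMF1, GPIHBP1, APOC2}.  Unknown keys raise, listing the
    panel's valid phenotype keys.
    """
    if phenotype not in panel.phenotype_keys:
        raise UnknownPhenotypeError(phenotype, panel.phenotype_keys)
    return {g.symbol for g in panel.genes if phenotype in g.phenotypes}


# ---------------------------------------------------------------------------
# target regions


def target_regions(panel: PanelDefinition) -> pd.DataFrame:
    """Flatten the panel into a sorted table of labeled target intervals.

    One row per (gene, target); columns chromosome/start/end/gene/label;
    rows sorted by (chromosome, start, gene).  Coordinates are 1-based
    inclusive.  This table defines the row order of depth matrices.
    """
    rows = []
    for g in panel.genes:
        labels = g.target_labels()
        for (start, end), label in zip(g.intervals, labels):
            rows.append(
                {
                    "chromosome": g.chromosome,
                    "start": start,
                    "end": end,
                    "gene": g.symbol,
                    "label": label,
                }
            )
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["chromosome", "start", "gene"], kind="mergesort"
    ).reset_index(drop=True)


def write_bed(panel: PanelDefinition, path) -> None:
    """Export target regions as BED (0-based half-open, 4th column gene)."""
    regions = target_regions(panel)
    with open(path, "w") as fh:
        for row in regions.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.start - 1}\t{row.end}\t{row.gene}\n")


# ---------------------------------------------------------------------------
# config IO

_GENE_COLUMNS = ["symbol", "category", "chromosome", "intervals", "phenotypes", "inheritance"]
_SNP_COLUMNS = [
    "snp_id",
    "trait",
    "raising_allele",
    "other_allele",
    "beta",
    "raising_allele_freq",
    "chromosome",
    "position",
]

GENES_FILENAME = "panel_genes.tsv"
SNPS_FILENAME = "score_snps.tsv"
META_FILENAME = "panel_meta.json"


def _parse_intervals(text: str, symbol: str):
    out = []
    for chunk in str(text).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            start_s, end_s = chunk.split("-")
            out.append((int(start_s), int(end_s)))
        except ValueError as exc:
            raise PanelConfigError(
                f"gene {symbol}: malformed interval {chunk!r}"
            ) from exc
    return tuple(out)


def load_panel(config_path) -> PanelDefinition:
    """Load and validate a panel from a config directory.

    ``config_path`` is a directory containing ``panel_genes.tsv`` and
    ``score_snps.tsv`` (and optionally ``panel_meta.json`` with
    ``micro_seq_snp_count``).  All invariants are checked; violations raise
    :class:`PanelConfigError` naming the offending record.
    """
    config_path = Path(config_path)
    genes_path = config_path / GENES_FILENAME
    snps_path = config_path / SNPS_FILENAME
    for p in (genes_path, snps_path):
        if not p.exists():
            raise PanelConfigError(f"missing panel config file: {p}")

    gene_table = pd.read_csv(genes_path, sep="\t", dtype=str)
    missing = set(_GENE_COLUMNS) - set(gene_table.columns)
    if missing:
        raise PanelConfigError(f"{genes_path}: missing columns {sorted(missing)}")
    genes = []
    for row in gene_table.itertuples(index=False):
        phenos = frozenset(
            p.strip() for p in str(row.phenotypes).split(",")
            if p.strip() and p.strip().lower() != "nan"
        )
        genes.append(
            GeneTarget(
                symbol=row.symbol,
                category=row.category,
                chromosome=row.chromosome,
                intervals=_parse_intervals(row.intervals, row.symbol),
                phenotypes=phenos,
                inheritance=row.inheritance,
            )
        )
    if not genes:
        raise PanelConfigError(f"{genes_path}: empty gene list")

    snp_table = pd.read_csv(snps_path, sep="\t", dtype=str)
    missing = set(_SNP_COLUMNS[:6]) - set(snp_table.columns)
    if missing:
        raise PanelConfigError(f"{snps_path}: missing columns {sorted(missing)}")
    snps = []
    for row in snp_table.itertuples(index=False):
        try:
            beta = float(row.beta)
            freq = float(row.raising_allele_freq)
        except ValueError as exc:
            raise PanelConfigError(
                f"score SNP {row.snp_id}: non-numeric beta/frequency"
            ) from exc
        snps.append(
            ScoreSNP(
                snp_id=row.snp_id,
                trait=row.trait,
                raising_allele=row.raising_allele,
                other_allele=row.other_allele,
                beta=beta,
                raising_allele_freq=freq,
                chromosome=getattr(row, "chromosome", "") or "",
                position=int(getattr(row, "position", 0) or 0),
            )
        )

    micro_count = 0
    meta_path = config_path / META_FILENAME
    if meta_path.exists():
        with open(meta_path) as fh:
            micro_count = int(json.load(fh).get("micro_seq_snp_count", 0))
    return PanelDefinition(genes=genes, score_snps=snps, micro_seq_snp_count=micro_count)


def save_panel(panel: PanelDefinition, config_path) -> None:
    """Write a panel back to TSV config; inverse of :func:`load_panel`."""
    config_path = Path(config_path)
    config_path.mkdir(parents=True, exist_ok=True)
    gene_rows = [
        {
            "symbol": g.symbol,
            "category": g.category,
            "chromosome": g.chromosome,
            "intervals": ";".join(f"{s}-{e}" for s, e in g.intervals),
            "phenotypes": ",".join(sorted(g.phenotypes)),
            "inheritance": g.inheritance,
        }
        for g in panel.genes
    ]
    pd.DataFrame(gene_rows, columns=_GENE_COLUMNS).to_csv(
        config_path / GENES_FILENAME, sep="\t", index=False
    )
    snp_rows = [
        {
            "snp_id": s.snp_id,
            "trait": s.trait,
            "raising_allele": s.raising_allele,
            "other_allele": s.other_allele,
            "beta": repr(s.beta),
            "raising_allele_freq": repr(s.raising_allele_freq),
            "chromosome": s.chromosome,
            "position": s.position,
        }
        for s in panel.score_snps
    ]
    pd.DataFrame(snp_rows, columns=_SNP_COLUMNS).to_csv(
        config_path / SNPS_FILENAME, sep="\t", index=False
    )
    with open(config_path / META_FILENAME, "w") as fh:
        json.dump({"micro_seq_snp_count": panel.micro_seq_snp_count}, fh)


def default_panel() -> PanelDefinition:
    """The shipped 69-gene / 35-score-SNP default configuration.

    Gene coordinates and score-SNP weights in this config are synthetic
    placeholders (see module docstring).
    """
    data_dir = resources.files("lipidpanel") / "data"
    with resources.as_file(data_dir) as path:
        return load_panel(path)
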