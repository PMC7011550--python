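"""Read-depth CNV calling against a reference panel, and unique-CNV tables.

The caller follows the reference-panel principle used by targeted capture
panels: a test sample's per-target mean read depth is compared to a group of
CNV-free reference samples.  Depth is normalized in two steps -- a
library-size correction scaling every sample column to a common median, then
a target-efficiency correction dividing each target row by its mean over the
reference samples -- so a diploid target sits at ratio ~1, a heterozygous
deletion near 0.5, a homozygous deletion near 0, and a heterozygous
duplication near 1.5.  Calls are maximal runs of consecutive in-gene targets
whose ratios fall in one copy-state band with |z| at or above a threshold,
where z is computed against the reference samples' per-target ratio
distribution.

Depth-only calling cannot distinguish same-span events with different
breakpoints; the optional ``breakpoint_tag`` on a call carries upstream
evidence (or simulation truth) for that purpose and participates in
unique-CNV aggregation.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

from .errors import CnvCallingError

CNV_STATES = ("het_deletion", "hom_deletion", "duplication")
MIN_REFERENCE_SAMPLES = 3


@dataclass
class CallerParams:
    """Tunable thresholds of the run-based caller.

    Bands are on the normalized depth ratio; ``z_min`` is the minimum
    absolute z-score per target; ``min_targets`` is the shortest run emitted
    (1 allows single-exon events); ``gap_tolerance`` is how many consecutive
    interior targets that fail state assignment (uncallable, or ratio
    drifting just outside the band) a run may bridge without breaking.  A
    target assigned a *different* copy state always breaks the run.  The
    default of 1 keeps multi-exon events whole: a long deletion or
    duplication occasionally has one target wander past a band edge, and
    splitting it would mislabel the event's span.

    ``z_combined`` is a run-level evidence threshold: a run is only emitted
    when |sum of its z-scores| / sqrt(run length) meets it.  With hundreds of
    targets per sample, a per-target cutoff alone would admit too many
    single-exon false calls; combining evidence across the run lets short
    events demand strong depth shifts while long events accumulate support.
    """

    min_targets: int = 1
    z_min: float = 3.0
    z_combined: float = 6.0
    hom_del_max: float = 0.15
    het_del_band: tuple = (0.35, 0.65)
    dup_band: tuple = (1.35, 1.75)
    gap_tolerance: int = 1


@dataclass
class DepthMatrix:
    """Per-target mean read depth, targets x samples.

    ``targets`` is a DataFrame with columns gene/label/chromosome/start/end
    in genomic order within each gene; ``samples`` the column ids; ``depth``
    a non-negative float array of shape (n_targets, n_samples).
    """

    targets: pd.DataFrame
    samples: list
    depth: np.ndarray

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.shape != (len(self.targets), len(self.samples)):
            raise CnvCallingError(
                f"depth shape {self.depth.shape} does not match "
                f"{len(self.targets)} targets x {len(self.samples)} samples"
            )
        if (self.depth < 0).any():
            raise CnvCallingError("negative depths in matrix")

    def column(self, sample_id: str) -> np.ndarray:
        try:
            return self.depth[:, self.samples.index(sample_id)]
        except ValueError as exc:
            raise CnvCallingError(f"sample {sample_id!r} not in matrix") from exc

    def to_tsv(self, path) -> None:
        depth_frame = pd.DataFrame(self.depth, columns=self.samples)
        frame = pd.concat(
            [self.targets.reset_index(drop=True), depth_frame], axis=1
        )
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "DepthMatrix":
        frame = pd.read_csv(path, sep="\t")
        meta_cols = ["gene", "label", "chromosome", "start", "end"]
        missing = set(meta_cols) - set(frame.columns)
        if missing:
            raise CnvCallingError(f"{path}: missing columns {sorted(missing)}")
        samples = [c for c in frame.columns if c not in meta_cols]
        return cls(
            targets=frame[meta_cols].reset_index(drop=True),
            samples=samples,
            depth=frame[samples].to_numpy(dtype=float),
        )


@dataclass
class CnvCall:
    """A deletion/duplication spanning contiguous panel targets."""

    sample_id: str
    gene: str
    region: str
    state: str
    breakpoint_tag: str = ""
    target_labels: tuple = ()
    ratios: tuple = ()
    zscores: tuple = ()

    def __post_init__(self):
        if self.state not in CNV_STATES:
            raise CnvCallingError(f"invalid CNV state {self.state!r}")

    @property
    def kind(self) -> str:
        """Copy direction: 'deletion' or 'duplication' (zygosity-blind)."""
        return "duplication" if self.state == "duplication" else "deletion"


_EXON_RE = re.compile(r"^Exon (\d+)$")


def format_region(first_label: str, last_label: str) -> str:
    """Human-readable span label from first/last target labels."""
    if first_label == last_label:
        return first_label
    m1, m2 = _EXON_RE.match(first_label), _EXON_RE.match(last_label)
    if m1 and m2:
        return f"Exons {m1.group(1)}–{m2.group(1)}"
    return f"{first_label} – {last_label}"


def normalize_depth(m: DepthMatrix, reference_samples=None):
    """Two-step normalization to diploid-relative ratios.

    Step 1 scales each sample column to the grand median depth
    (library-size correction); step 2 divides each target row by its mean
    over the reference samples (target-efficiency correction), so diploid
    targets sit near ratio 1.  Returns ``(ratios, uncallable)`` where
    ``ratios`` is a DepthMatrix of normalized ratios and ``uncallable`` a
    boolean mask of targets whose reference row mean is zero (excluded from
    calling).
    """
    if not m.samples:
        raise CnvCallingError("depth matrix has no samples")
    col_medians = np.median(m.depth, axis=0)
    if (col_medians <= 0).any():
        bad = [s for s, cm in zip(m.samples, col_medians) if cm <= 0]
        raise CnvCallingError(f"all-zero (or zero-median) sample column(s): {bad}")
    scaled = m.depth * (np.median(col_medians) / col_medians)

    if reference_samples is None:
        ref_idx = np.arange(len(m.samples))
    else:
        ref_idx = np.array([m.samples.index(s) for s in reference_samples])
    row_mean = scaled[:, ref_idx].mean(axis=1)
    uncallable = row_mean <= 0
    safe = np.where(uncallable, 1.0, row_mean)
    ratios = scaled / safe[:, None]
    ratios[uncallable, :] = np.nan
    return replace(m, depth=ratios), uncallable


def _state_of(ratio: float, z: float, p: CallerParams) -> Optional[str]:
    if not np.isfinite(ratio):
        return None
    if ratio < p.hom_del_max and z <= -p.z_min:
        return "hom_deletion"
    if p.het_del_band[0] <= ratio <= p.het_del_band[1] and z <= -p.z_min:
        return "het_deletion"
    if p.dup_band[0] <= ratio <= p.dup_band[1] and z >= p.z_min:
        return "duplication"
    return None


def call_cnvs(
    m: DepthMatrix,
    test_sample: str,
    reference_samples,
    params: CallerParams = None,
) -> list[CnvCall]:
    """Call CNVs for one test sample against a CNV-free reference panel.

    Deterministic given inputs.  The test sample must not be in the
    reference set and the reference set must have at least 3 samples.
    Uncallable targets (zero reference depth) break runs unless within
    ``gap_tolerance``.
    """
    params = params or CallerParams()
    reference_samples = list(reference_samples)
    if test_sample in reference_samples:
        raise CnvCallingError("test sample must not be in the reference set")
    if len(reference_samples) < MIN_REFERENCE_SAMPLES:
        raise CnvCallingError(
            f"need >= {MIN_REFERENCE_SAMPLES} reference samples, "
            f"got {len(reference_samples)}"
        )
    ratios, uncallable = normalize_depth(m, reference_samples)
    ref_idx = np.array([m.samples.index(s) for s in reference_samples])
    ref_ratios = ratios.depth[:, ref_idx]
    mean_ref = ref_ratios.mean(axis=1)
    sd_ref = ref_ratios.std(axis=1, ddof=1)
    sd_ref = np.where(sd_ref <= 0, np.nan, sd_ref)
    test = ratios.depth[:, m.samples.index(test_sample)]
    with np.errstate(invalid="ignore"):
        z = (test - mean_ref) / sd_ref

    calls: list[CnvCall] = []
    targets = m.targets
    for gene, idx in targets.groupby("gene", sort=False).groups.items():
        idx = list(idx)
        run: list[int] = []
        run_state: Optional[str] = None
        gap = 0

        def flush():
            nonlocal run, run_state, gap
            if (
                run_state is not None
                and len(run) >= params.min_targets
                and abs(sum(z[i] for i in run)) / math.sqrt(len(run))
                >= params.z_combined
            ):
                labels = [targets.at[i, "label"] for i in run]
                calls.append(
                    CnvCall(
                        sample_id=test_sample,
                        gene=gene,
                        region=format_region(labels[0], labels[-1]),
                        state=run_state,
                        target_labels=tuple(labels),
                        ratios=tuple(round(float(test[i]), 4) for i in run),
                        zscores=tuple(round(float(z[i]), 3) for i in run),
                    )
                )
            run, run_state, gap = [], None, 0

        for i in idx:
            no_state = uncallable[i] or not np.isfinite(z[i])
            state = None if no_state else _state_of(test[i], z[i], params)
            if state is None:
                # gap target: bridge it while the run can tolerate gaps
                if run_state is not None:
                    gap += 1
                    if gap > params.gap_tolerance:
                        flush()
                continue
            if state == run_state:
                run.append(i)
                gap = 0
            else:
                flush()
                run, run_state = [i], state
        flush()
    return calls


def call_cohort(
    m: DepthMatrix, test_samples, reference_samples, params: CallerParams = None
) -> list[CnvCall]:
    """Call CNVs for several test samples against one reference panel."""
    calls: list[CnvCall] = []
    for s in test_samples:
        calls.extend(call_cnvs(m, s, reference_samples, params))
    return calls


# ---------------------------------------------------------------------------
# unique-CNV aggregation


@dataclass(frozen=True)
class UniqueCnvRow:
    gene: str
    region: str
    kind: str  # deletion | duplication
    state_summary: str  # e.g. "het x10" or "hom x2, het"
    breakpoint_tag: str
    instances_observed: int


@dataclass
class UniqueCnvTable:
    """Catalogue of distinct CNVs with observation counts.

    A unique CNV is identified by (gene, region, copy direction,
    breakpoint_tag): het and hom observations of the same deletion are one
    unique CNV (the zygosity breakdown lives in ``state_summary``), while
    same-span events with distinct breakpoint tags stay distinct rows.
    """

    rows: list = field(default_factory=list)

    @property
    def unique_count(self) -> int:
        return len(self.rows)

    @property
    def instance_count(self) -> int:
        return sum(r.instances_observed for r in self.rows)

    @property
    def totals(self) -> tuple:
        return (self.unique_count, self.instance_count)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])


def _state_summary(kind: str, states) -> str:
    if kind == "duplication":
        return "duplication"
    parts = []
    for zyg, tag in (("hom_deletion", "hom"), ("het_deletion", "het")):
        n = sum(1 for s in states if s == zyg)
        if n == 1:
            parts.append(tag)
        elif n > 1:
            parts.append(f"{tag} ×{n}")
    return ", ".join(parts)


def aggregate_unique(calls) -> UniqueCnvTable:
    """Aggregate per-sample calls into the unique-CNV catalogue."""
    groups: dict[tuple, list] = {}
    order: list[tuple] = []
    for c in calls:
        key = (c.gene, c.region, c.kind, c.breakpoint_tag)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(c.state)
    rows = [
        UniqueCnvRow(
            gene=gene,
            region=region,
            kind=kind,
            state_summary=_state_summary(kind, groups[key]),
            breakpoint_tag=tag,
            instances_observed=len(groups[key]),
        )
        for key in order
        for gene, region, kind, tag in [key]
    ]
    return UniqueCnvTable(rows=rows)


def load_cnv_catalogue(path=None) -> list[CnvCall]:
    """Load an instance-level CNV catalogue TSV as CnvCall records.

    With no path, loads the catalogue of published unique CNVs shipped with
    the package (191 observations of 77 distinct events).
    """
    if path is None:
        data = resources.files("lipidpanel") / "data" / "cnv_catalogue.tsv"
        with resources.as_file(data) as p:
            frame = pd.read_csv(p, sep="\t", keep_default_na=False)
    else:
        frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        CnvCall(
            sample_id=row.sample_id,
            gene=row.gene,
            region=row.region,
            state=row.state,
            breakpoint_tag=str(row.breakpoint_tag),
        )
        for row in frame.itertuples(index=False)
    ]
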