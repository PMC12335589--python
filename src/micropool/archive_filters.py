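"""Consolidation of per-project genus tables and the archive filter cascade.

Per-project genus-level count tables are merged into one archive-wide
table (union of taxa, zeros for taxa a project never observed, read totals
conserved exactly).  The archive is then cleaned by a fixed five-stage
cascade, each stage deleting whole rows or columns and never altering a
surviving cell:

1. drop samples with fewer than ``min_sample_reads`` total reads;
2. drop taxa with fewer than ``min_taxon_reads`` reads summed over the
   surviving samples;
3. drop taxa present (count > 0) in fewer than ``min_taxon_prevalence``
   samples;
4. re-apply stage 1 on the remaining counts (rare-taxon removal may have
   pushed a sample back below the depth floor);
5. drop samples whose fraction of reads on phylum-unclassified taxa,
   computed on the post-stage-3 counts, exceeds ``max_unclassified_frac``.

All inequalities are strict: a sample with exactly the threshold survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io_core import (
    UNCLASSIFIED_PHYLUM,
    GenusCountTable,
    ValidationError,
    get_logger,
)

__all__ = [
    "FilterStage",
    "FilterReport",
    "consolidate_tables",
    "filter_archive",
    "DEFAULT_MIN_SAMPLE_READS",
    "DEFAULT_MIN_TAXON_READS",
    "DEFAULT_MIN_TAXON_PREVALENCE",
    "DEFAULT_MAX_UNCLASSIFIED_FRAC",
]

logger = get_logger(__name__)

DEFAULT_MIN_SAMPLE_READS = 10_000
DEFAULT_MIN_TAXON_READS = 80
DEFAULT_MIN_TAXON_PREVALENCE = 3
DEFAULT_MAX_UNCLASSIFIED_FRAC = 0.10


@dataclass
class FilterStage:
    """Record of one cascade stage."""

    stage: str
    kind: Literal["sample", "taxon"]
    threshold: float
    n_removed: int
    removed_ids: list[str]
    #: removed fraction of the entities entering the stage
    fraction_removed: float


@dataclass
class FilterReport:
    """Per-stage removal tallies; reconciles input vs output dimensions."""

    stages: list[FilterStage] = field(default_factory=list)
    input_samples: int = 0
    input_taxa: int = 0
    output_samples: int = 0
    output_taxa: int = 0

    def validate(self) -> None:
        removed_samples = sum(s.n_removed for s in self.stages if s.kind == "sample")
        removed_taxa = sum(s.n_removed for s in self.stages if s.kind == "taxon")
        if removed_samples != self.input_samples - self.output_samples:
            raise ValidationError("sample removals do not reconcile with dimensions")
        if removed_taxa != self.input_taxa - self.output_taxa:
            raise ValidationError("taxon removals do not reconcile with dimensions")

    def removed_samples(self) -> set[str]:
        return {i for s in self.stages if s.kind == "sample" for i in s.removed_ids}

    def removed_taxa(self) -> set[str]:
        return {i for s in self.stages if s.kind == "taxon" for i in s.removed_ids}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": [s.stage for s in self.stages],
                "kind": [s.kind for s in self.stages],
                "threshold": [s.threshold for s in self.stages],
                "n_removed": [s.n_removed for s in self.stages],
                "fraction_removed": [s.fraction_removed for s in self.stages],
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def consolidate_tables(tables: Sequence[GenusCountTable]) -> GenusCountTable:
    """Merge per-project tables into one archive-wide table.

    The output taxon set is the union of the inputs'; a sample's count for
    a taxon its source project never reported is 0.  Sample ids must be
    globally unique; taxon metadata must agree across projects for shared
    taxa.  Total reads are conserved exactly.
    """
    if not tables:
        raise ValidationError("no tables to consolidate")
    seen: dict[str, str] = {}
    for t in tables:
        project = str(t.sample_meta["project_id"].iloc[0]) if t.n_samples else "?"
        for sid in t.sample_ids:
            if sid in seen:
                raise ValidationError(
                    f"duplicate sample_id {sid!r} in projects "
                    f"{seen[sid]!r} and {project!r}"
                )
            seen[sid] = project

    counts = pd.concat([t.counts for t in tables], axis=0).fillna(0).astype(np.int64)
    sample_meta = pd.concat([t.sample_meta for t in tables], axis=0)

    taxon_meta = pd.concat([t.taxon_meta for t in tables], axis=0)
    taxon_meta = taxon_meta[~taxon_meta.index.duplicated(keep="first")]
    # guard against conflicting lineage labels for a shared taxon id
    all_meta = pd.concat([t.taxon_meta for t in tables], axis=0)
    conflicting = all_meta.groupby(level=0).nunique()
    bad = conflicting[(conflicting > 1).any(axis=1)]
    if len(bad):
        raise ValidationError(
            f"conflicting taxon metadata for {bad.index[0]!r} across projects"
        )
    taxon_meta = taxon_meta.loc[counts.columns]

    return GenusCountTable(counts=counts, sample_meta=sample_meta, taxon_meta=taxon_meta)


def filter_archive(
    table: GenusCountTable,
    min_sample_reads: int = DEFAULT_MIN_SAMPLE_READS,
    min_taxon_reads: int = DEFAULT_MIN_TAXON_READS,
    min_taxon_prevalence: int = DEFAULT_MIN_TAXON_PREVALENCE,
    max_unclassified_frac: float = DEFAULT_MAX_UNCLASSIFIED_FRAC,
    taxon_sums_after_sample_filter: bool = True,
) -> tuple[GenusCountTable, FilterReport]:
    """Run the five-stage sample/taxon filter cascade.

    ``taxon_sums_after_sample_filter`` controls whether the stage-2 taxon
    read sums are computed on the stage-1 survivors (default) or on the
    full input table.

    Returns the filtered table and a :class:`FilterReport`.  Removing all
    samples is not an error: the report is complete and a warning logged.
    """
    if min(min_sample_reads, min_taxon_reads, min_taxon_prevalence) <= 0:
        raise ValidationError("filter thresholds must be positive")
    report = FilterReport(input_samples=table.n_samples, input_taxa=table.n_taxa)
    counts = table.counts

    def record(stage: str, kind: str, threshold: float, removed: pd.Index, n_in: int):
        report.stages.append(
            FilterStage(
                stage=stage,
                kind=kind,  # type: ignore[arg-type]
                threshold=threshold,
                n_removed=len(removed),
                removed_ids=[str(i) for i in removed],
                fraction_removed=len(removed) / n_in if n_in else 0.0,
            )
        )

    # stage 1: low-depth samples
    row_sums = counts.sum(axis=1)
    drop = counts.index[row_sums < min_sample_reads]
    record("low_depth_samples", "sample", min_sample_reads, drop, len(counts))
    stage1 = counts.drop(index=drop)

    # stage 2: low-read taxa
    basis = stage1 if taxon_sums_after_sample_filter else counts
    col_sums = basis.sum(axis=0)
    drop = stage1.columns[col_sums.loc[stage1.columns] < min_taxon_reads]
    record("low_read_taxa", "taxon", min_taxon_reads, drop, stage1.shape[1])
    stage2 = stage1.drop(columns=drop)

    # stage 3: low-prevalence taxa (presence = count > 0, on surviving samples)
    prevalence = (stage2 > 0).sum(axis=0)
    drop = stage2.columns[prevalence < min_taxon_prevalence]
    record("low_prevalence_taxa", "taxon", min_taxon_prevalence, drop, stage2.shape[1])
    stage3 = stage2.drop(columns=drop)

    # stage 4: re-check sample depth on the remaining counts
    row_sums = stage3.sum(axis=1)
    drop = stage3.index[row_sums < min_sample_reads]
    record("low_depth_samples_recheck", "sample", min_sample_reads, drop, len(stage3))
    stage4 = stage3.drop(index=drop)

    # stage 5: phylum-unclassified read fraction on the post-stage-3 counts
    unclassified = table.taxon_meta.loc[stage4.columns, "phylum"] == UNCLASSIFIED_PHYLUM
    totals = stage4.sum(axis=1).astype(float)
    uncl_reads = stage4.loc[:, unclassified.to_numpy()].sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, uncl_reads / totals.replace(0, 1), 0.0)
    drop = stage4.index[frac > max_unclassified_frac]
    record("unclassified_phylum_samples", "sample", max_unclassified_frac, drop, len(stage4))
    stage5 = stage4.drop(index=drop)

    report.output_samples, report.output_taxa = stage5.shape
    report.validate()
    if report.output_samples == 0:
        logger.warning("filter cascade removed every sample")

    filtered = GenusCountTable(
        counts=stage5.copy(),
        sample_meta=table.sample_meta.loc[stage5.index].copy(),
        taxon_meta=table.taxon_meta.loc[stage5.columns].copy(),
    )
    return filtered, report
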