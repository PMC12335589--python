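"""Project-level quality control on denoising read-tracking tables.

Amplicon archives assembled from many independent bioprojects inherit very
uneven sequencing quality.  Rather than inspecting raw reads, whole
bioprojects are accepted or rejected from the per-sample read counts the
denoising stage reports: reads in, reads entering chimera removal, and
non-chimeric reads out.  Two rules decide a project's fate:

1. the project-wide fraction of non-chimeric reads over input reads must
   not fall below 50% (fails when strictly below), and
2. among the first ten samples in manifest order, fewer than five may show
   a chimeric fraction strictly above 25%.

A paired-end project failing either rule is re-run single-end (reverse
reads dropped); a single-end project — or a re-run that fails again — is
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .io_core import ValidationError, get_logger

__all__ = [
    "ReadTrackingTable",
    "QCVerdict",
    "read_tracking_tables",
    "write_verdicts",
    "assess_project_quality",
    "plan_reanalysis",
]

logger = get_logger(__name__)

TRACKING_COLUMNS = ("sample_id", "input_reads", "prechimera_reads", "nonchimeric_reads")

#: project fails when nonchimeric/input is strictly below this
MIN_NONCHIMERIC_FRACTION = 0.5
#: a sample is "chimera-heavy" when its chimeric fraction is strictly above this
MAX_SAMPLE_CHIMERIC_FRACTION = 0.25
#: the project fails when at least this many of the first window are chimera-heavy
CHIMERA_RULE_MIN_COUNT = 5
#: manifest-order window inspected by the chimera rule
CHIMERA_RULE_WINDOW = 10


@dataclass
class ReadTrackingTable:
    """Per-sample read counts at the denoising stages for one project.

    Row order is the project manifest order and is significant: the
    chimera rule inspects the first ten rows as supplied.
    """

    project_id: str
    samples: pd.DataFrame  # columns TRACKING_COLUMNS, manifest order

    def __post_init__(self) -> None:
        missing = set(TRACKING_COLUMNS) - set(self.samples.columns)
        if missing:
            raise ValidationError(
                f"tracking table for {self.project_id} missing columns "
                f"{sorted(missing)}"
            )
        if len(self.samples) == 0:
            raise ValidationError(f"tracking table for {self.project_id} is empty")
        s = self.samples
        for low, high in (
            ("nonchimeric_reads", "prechimera_reads"),
            ("prechimera_reads", "input_reads"),
        ):
            bad = s[low] > s[high]
            if bad.any():
                sid = s.loc[bad, "sample_id"].iloc[0]
                raise ValidationError(
                    f"{self.project_id}/{sid}: {low} exceeds {high}"
                )
        if (s[list(TRACKING_COLUMNS[1:])].to_numpy() < 0).any():
            raise ValidationError(f"{self.project_id}: negative read count")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class QCVerdict:
    """Outcome of the two project-level quality rules."""

    project_id: str
    pass_nonchimeric_fraction: bool
    pass_chimera_rule: bool
    overall: Literal["pass", "fail"]
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = (
            "pass"
            if (self.pass_nonchimeric_fraction and self.pass_chimera_rule)
            else "fail"
        )
        if self.overall != expected:
            raise ValidationError(
                f"{self.project_id}: overall verdict inconsistent with criteria"
            )


def assess_project_quality(
    tracking: ReadTrackingTable,
    chimera_denominator: Literal["prechimera", "input"] = "prechimera",
) -> QCVerdict:
    """Apply both quality rules to one project's tracking table.

    Rule 1 uses project-wide totals: ``sum(nonchimeric) / sum(input)``,
    failing when strictly below 0.5.  Rule 2 computes each of the first
    ``min(10, n)`` samples' chimeric fraction
    ``1 - nonchimeric / denominator`` and fails when 5 or more exceed
    0.25 strictly.  ``chimera_denominator`` selects the denominator:
    reads entering chimera removal (default) or raw input reads.
    """
    s = tracking.samples
    total_input = int(s["input_reads"].sum())
    total_nonchimeric = int(s["nonchimeric_reads"].sum())
    nonchimeric_fraction = (
        total_nonchimeric / total_input if total_input > 0 else 0.0
    )
    pass_fraction = not (nonchimeric_fraction < MIN_NONCHIMERIC_FRACTION)

    window = s.iloc[: CHIMERA_RULE_WINDOW]
    denom_col = "prechimera_reads" if chimera_denominator == "prechimera" else "input_reads"
    denom = window[denom_col].to_numpy(dtype=float)
    nonchim = window["nonchimeric_reads"].to_numpy(dtype=float)
    zero = denom == 0
    if zero.any():
        for sid in window.loc[zero, "sample_id"]:
            logger.warning(
                "%s/%s: zero %s reads; chimeric fraction defined as 0",
                tracking.project_id,
                sid,
                denom_col,
            )
    with np.errstate(divide="ignore", invalid="ignore"):
        chimeric_fraction = np.where(zero, 0.0, 1.0 - nonchim / np.where(zero, 1, denom))
    n_heavy = int((chimeric_fraction > MAX_SAMPLE_CHIMERIC_FRACTION).sum())
    pass_chimera = n_heavy < CHIMERA_RULE_MIN_COUNT

    overall: Literal["pass", "fail"] = (
        "pass" if (pass_fraction and pass_chimera) else "fail"
    )
    return QCVerdict(
        project_id=tracking.project_id,
        pass_nonchimeric_fraction=pass_fraction,
        pass_chimera_rule=pass_chimera,
        overall=overall,
        details={
            "total_input_reads": total_input,
            "total_nonchimeric_reads": total_nonchimeric,
            "nonchimeric_fraction": nonchimeric_fraction,
            "window_size": len(window),
            "chimeric_fractions": chimeric_fraction.tolist(),
            "n_chimera_heavy": n_heavy,
            "chimera_denominator": chimera_denominator,
        },
    )


def plan_reanalysis(
    verdict: QCVerdict,
    layout: str,
) -> Literal["accept", "rerun_single_end", "discard"]:
    """Decide a project's fate from its verdict and library layout.

    A passing project is accepted regardless of layout.  A failing
    paired-end project is re-analysed single-end (its re-run verdict, with
    ``layout="single"``, then decides accept vs discard).  A failing
    single-end project is discarded; an unknown layout offers no re-run
    and is treated as single (logged).
    """
    if verdict.overall == "pass":
        return "accept"
    if layout == "paired":
        return "rerun_single_end"
    if layout not in ("single", "paired"):
        logger.warning(
            "%s: unknown library layout; treating as single-end (no rerun)",
            verdict.project_id,
        )
    return "discard"


# ---------------------------------------------------------------------------
# TSV interface
# ---------------------------------------------------------------------------


def read_tracking_tables(path: str | Path) -> list[ReadTrackingTable]:
    """Read a tracking TSV (one or more projects) preserving row order.

    Columns: project_id, sample_id, input_reads, prechimera_reads,
    nonchimeric_reads.  Rows are grouped by project in file order.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"project_id": str, "sample_id": str})
    required = {"project_id", *TRACKING_COLUMNS}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"tracking file missing columns {sorted(missing)}")
    tables = []
    for project_id, group in frame.groupby("project_id", sort=False):
        tables.append(
            ReadTrackingTable(
                project_id=str(project_id),
                samples=group[list(TRACKING_COLUMNS)].reset_index(drop=True),
            )
        )
    return tables


def write_verdicts(
    verdicts: list[tuple[QCVerdict, str]],
    path: str | Path,
) -> pd.DataFrame:
    """Write (verdict, planned action) pairs to a verdict TSV."""
    rows = []
    for verdict, action in verdicts:
        rows.append(
            {
                "project_id": verdict.project_id,
                "nonchimeric_fraction": verdict.details["nonchimeric_fraction"],
                "pass_nonchimeric_fraction": verdict.pass_nonchimeric_fraction,
                "n_chimera_heavy": verdict.details["n_chimera_heavy"],
                "pass_chimera_rule": verdict.pass_chimera_rule,
                "overall": verdict.overall,
                "action": action,
            }
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(path, sep="\t", index=False)
    return frame
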