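"""Taxon accumulation by Monte-Carlo subsampling of samples.

How many distinct genera does a region's sampling effort reveal, and how
fast does that number grow as more samples are collected?  Counts are
binarised to presence/absence; for each subsampling depth k the estimator
draws k samples uniformly without replacement, counts the taxa present in
at least one drawn sample, and repeats over many iterations to report a
mean and sample SD.  A curve that plateaus before the full sample count
suggests the prevalent taxa of the group have all been observed.

The Monte-Carlo estimator has an exact counterpart: given the occupancy
m_t of each taxon (the number of samples containing it) among n samples,
the expected number of distinct taxa in a uniform k-subset is

    E[U_k] = sum_t [ 1 - C(n - m_t, k) / C(n, k) ],

evaluated in log-space for stability.  This closed form is exposed as an
oracle for the simulation and is used throughout the test-suite.

An optional rarefaction step downsamples each sample's reads without
replacement to a common depth before binarisation, removing depth-driven
richness bias; samples below the depth are dropped from that regime only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io_core import GenusCountTable, ValidationError, get_logger

__all__ = [
    "AccumulationCurve",
    "OccupancyVector",
    "DEFAULT_DEPTH_GRID",
    "RAREFACTION_PRESETS",
    "binarize",
    "rarefy",
    "rarefy_table",
    "expected_unique_taxa",
    "accumulation_curve",
    "group_accumulation",
    "curves_to_frame",
]

logger = get_logger(__name__)

#: default subsampling depth grid, clipped per group
DEFAULT_DEPTH_GRID = (5, 10, 25, 50, 100, 250, 500, 1000, 2000, 3000)

#: published rarefaction regimes (reads per sample)
RAREFACTION_PRESETS = (9000, 1000)

Grouping = Literal["country", "continent", "setting"]


@dataclass
class OccupancyVector:
    """Per-taxon occupancy (number of samples containing the taxon).

    Taxa with zero occupancy are excluded; this is the sufficient
    statistic for the exact accumulation expectation.
    """

    m: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=np.int64)
        if (self.m < 1).any() or (self.m > self.n).any():
            raise ValidationError("occupancies must lie in [1, n]")

    @classmethod
    def from_presence(cls, presence) -> "OccupancyVector":
        arr = np.asarray(presence, dtype=bool)
        m = arr.sum(axis=0)
        return cls(m=m[m > 0], n=arr.shape[0])


@dataclass
class AccumulationCurve:
    """Mean/SD of unique-taxon counts per subsampling depth for one group."""

    group: str
    depths: np.ndarray
    mean_unique_taxa: np.ndarray
    sd_unique_taxa: np.ndarray
    n_iter: int
    seed: int
    n_samples: int = 0
    n_dropped_rarefaction: int = 0

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if len(self.depths) and (np.diff(self.depths) <= 0).any():
            raise ValidationError("depths must be strictly increasing")
        if (np.asarray(self.sd_unique_taxa) < 0).any():
            raise ValidationError("negative SD")


def binarize(table: GenusCountTable) -> pd.DataFrame:
    """Presence/absence matrix: 1 where count > 0, else 0."""
    return (table.counts > 0).astype(np.int8)


def rarefy(sample_counts, depth: int, seed: int) -> np.ndarray:
    """Draw ``depth`` reads uniformly without replacement from one sample.

    The input vector is treated as a multiset of reads; the output sums
    exactly to ``depth`` and never exceeds the input per taxon
    (multivariate hypergeometric draw).
    """
    counts = np.asarray(sample_counts, dtype=np.int64)
    if (counts < 0).any():
        raise ValidationError("negative counts")
    total = int(counts.sum())
    if depth < 0:
        raise ValidationError("depth must be non-negative")
    if total < depth:
        raise ValidationError(f"sample has {total} reads, fewer than depth {depth}")
    if total == depth:
        return counts.copy()
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth)


def rarefy_table(
    table: GenusCountTable, depth: int, seed: int
) -> tuple[GenusCountTable, int]:
    """Rarefy every sample to ``depth`` reads; drop samples below it.

    Returns the rarefied table and the number of dropped samples (the
    drop applies to this regime only; the input table is untouched).
    """
    totals = table.counts.sum(axis=1)
    keep = totals[totals >= depth].index
    n_dropped = table.n_samples - len(keep)
    if n_dropped:
        logger.warning(
            "rarefaction to %d reads drops %d of %d samples",
            depth,
            n_dropped,
            table.n_samples,
        )
    if len(keep) == 0:
        raise ValidationError(f"no sample reaches rarefaction depth {depth}")
    rng = np.random.default_rng(seed)
    sub = table.counts.loc[keep]
    out = np.empty(sub.shape, dtype=np.int64)
    arr = sub.to_numpy(dtype=np.int64)
    for i in range(arr.shape[0]):
        total = int(arr[i].sum())
        if total == depth:
            out[i] = arr[i]
        else:
            out[i] = rng.multivariate_hypergeometric(arr[i], depth)
    counts = pd.DataFrame(out, index=sub.index, columns=sub.columns)
    return (
        GenusCountTable(
            counts=counts,
            sample_meta=table.sample_meta.loc[keep].copy(),
            taxon_meta=table.taxon_meta.copy(),
        ),
        n_dropped,
    )


def expected_unique_taxa(occ: OccupancyVector, k: int) -> float:
    """Exact expected number of distinct taxa in a uniform k-subset.

    sum_t [1 - C(n - m_t, k) / C(n, k)], computed in log-space.
    """
    n = occ.n
    if k < 0 or k > n:
        raise ValidationError(f"k={k} outside [0, {n}]")
    if k == 0:
        return 0.0
    m = occ.m
    absent = np.zeros(len(m))
    feasible = (n - m) >= k  # otherwise the taxon is certainly drawn
    nm = (n - m)[feasible].astype(float)
    log_ratio = (
        gammaln(nm + 1)
        - gammaln(nm - k + 1)
        - (gammaln(n + 1.0) - gammaln(n - k + 1.0))
    )
    absent[feasible] = np.exp(log_ratio)
    return float((1.0 - absent).sum())


# ---------------------------------------------------------------------------
# Monte-Carlo estimator
# ---------------------------------------------------------------------------

_POPCOUNT = np.unpackbits(np.arange(256, dtype=np.uint8)[:, None], axis=1).sum(
    axis=1
).astype(np.int64)


def accumulation_curve(
    presence,
    depths: Sequence[int],
    n_iter: int = 1000,
    seed: int = 0,
    group: str = "all",
) -> AccumulationCurve:
    """Monte-Carlo accumulation curve over a presence matrix.

    For each depth k, draws k samples (rows) without replacement and
    counts taxa present in at least one of them, repeated ``n_iter``
    times.  Deterministic for a fixed seed.  The SD reported is the
    sample SD across iterations (ddof=1; zero when k equals the group
    size, as every draw is then the full set).
    """
    arr = np.asarray(presence, dtype=bool)
    if arr.size == 0:
        raise ValidationError("empty presence matrix")
    n = arr.shape[0]
    depths = np.asarray(sorted(set(int(d) for d in depths)), dtype=np.int64)
    if len(depths) == 0:
        raise ValidationError("no depths requested")
    if depths[0] < 1 or depths[-1] > n:
        raise ValidationError(f"depths must lie in [1, {n}]")
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")

    packed = np.packbits(arr, axis=1)  # samples x ceil(T/8) bytes
    rng = np.random.default_rng(seed)
    means = np.empty(len(depths))
    sds = np.empty(len(depths))
    uniques = np.empty(n_iter, dtype=np.int64)
    for di, k in enumerate(depths):
        if k == n:
            # every draw is the full sample set; no randomness needed
            uniques[:] = int(_POPCOUNT[np.bitwise_or.reduce(packed, axis=0)].sum())
        else:
            for it in range(n_iter):
                idx = rng.choice(n, size=int(k), replace=False)
                union = np.bitwise_or.reduce(packed[idx], axis=0)
                uniques[it] = _POPCOUNT[union].sum()
        means[di] = uniques.mean()
        sds[di] = uniques.std(ddof=1) if n_iter > 1 else 0.0
    return AccumulationCurve(
        group=group,
        depths=depths,
        mean_unique_taxa=means,
        sd_unique_taxa=sds,
        n_iter=n_iter,
        seed=seed,
        n_samples=n,
    )


def _clip_depths(
    depths: Sequence[int] | None, n: int, include_full_depth: bool
) -> list[int]:
    grid = list(DEFAULT_DEPTH_GRID if depths is None else depths)
    clipped = sorted({d for d in grid if 1 <= d <= n})
    if include_full_depth and n not in clipped:
        clipped.append(n)
    return clipped


def group_accumulation(
    table: GenusCountTable,
    grouping: Grouping = "country",
    depths: Sequence[int] | None = None,
    n_iter: int = 1000,
    seed: int = 0,
    rarefaction_depth: int | None = None,
    include_full_depth: bool = True,
) -> list[AccumulationCurve]:
    """Accumulation curves per country, per setting, or continent-wide.

    The depth grid (default :data:`DEFAULT_DEPTH_GRID`) is clipped to each
    group's sample count; the group's full size is appended unless
    ``include_full_depth`` is off.  When ``rarefaction_depth`` is set,
    samples are rarefied first and those below the depth are dropped from
    this analysis only (count recorded on each curve).  Groups with no
    samples are skipped with a warning; samples with group label
    "unknown" form their own group under ``setting`` grouping.
    """
    n_dropped = 0
    if rarefaction_depth is not None:
        table, n_dropped = rarefy_table(table, rarefaction_depth, seed)
    presence = binarize(table).to_numpy(dtype=bool)

    if grouping == "continent":
        groups = {"continent": np.arange(table.n_samples)}
    else:
        key = "country" if grouping == "country" else "setting"
        labels = table.sample_meta[key].to_numpy()
        groups = {
            str(g): np.flatnonzero(labels == g) for g in pd.unique(labels)
        }
        groups = dict(sorted(groups.items()))

    curves = []
    for gi, (label, idx) in enumerate(groups.items()):
        if len(idx) == 0:
            logger.warning("group %s has no samples; skipped", label)
            continue
        grid = _clip_depths(depths, len(idx), include_full_depth)
        curve = accumulation_curve(
            presence[idx],
            grid,
            n_iter=n_iter,
            seed=seed + gi,
            group=label,
        )
        curve.n_dropped_rarefaction = n_dropped
        curves.append(curve)
    return curves


def curves_to_frame(curves: Sequence[AccumulationCurve]) -> pd.DataFrame:
    """Long-format frame (group, depth, mean, sd, n_iter) for TSV output."""
    rows = []
    for c in curves:
        for d, m, s in zip(c.depths, c.mean_unique_taxa, c.sd_unique_taxa):
            rows.append(
                {
                    "group": c.group,
                    "depth": int(d),
                    "mean_unique_taxa": float(m),
                    "sd_unique_taxa": float(s),
                    "n_iter": c.n_iter,
                }
            )
    return pd.DataFrame(rows)
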