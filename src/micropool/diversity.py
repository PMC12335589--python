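"""Alpha diversity, pairwise dissimilarity, per-country uniqueness and the
Mantel test.

Alpha diversity is summarised per sample as observed richness (taxa with a
positive count) and the Shannon index H = -sum p_i log p_i over the
sample's relative abundances (natural log by default).  Beta diversity
offers binary Jaccard on presence sets, Bray-Curtis on counts, and the
quantitative Jaccard variant 2B/(1+B) derived from Bray-Curtis (the
abundance-based form the vegan package returns on counts).

Per-country "uniqueness" is the distribution of all pairwise distances
among a country's samples: a higher median means fewer shared genera
between two people from that country, i.e. a more heterogeneous local
microbiome.  The Mantel test correlates two distance matrices over the
same samples via joint row/column permutation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .io_core import GenusCountTable, ValidationError, get_logger

__all__ = [
    "AlphaTable",
    "UniquenessSummary",
    "observed_richness",
    "shannon",
    "jaccard_distance",
    "bray_curtis",
    "pairwise_distances",
    "alpha_table",
    "country_uniqueness",
    "aggregate_to_phylum",
    "relative_abundance",
    "mantel_test",
]

logger = get_logger(__name__)

Metric = Literal["jaccard", "braycurtis"]
JaccardMode = Literal["binary", "quantitative"]


# ---------------------------------------------------------------------------
# Scalar metrics
# ---------------------------------------------------------------------------


def observed_richness(sample_counts) -> int:
    """Number of taxa with a strictly positive count."""
    counts = np.asarray(sample_counts)
    if (counts < 0).any():
        raise ValidationError("negative counts")
    return int((counts > 0).sum())


def shannon(sample_counts, log_base: float | None = None) -> float:
    """Shannon diversity -sum p_i log(p_i); natural log unless a base is given."""
    counts = np.asarray(sample_counts, dtype=float)
    if (counts < 0).any():
        raise ValidationError("negative counts")
    total = counts.sum()
    if total == 0:
        raise ValidationError("Shannon diversity is undefined for an all-zero sample")
    p = counts[counts > 0] / total
    h = float(-(p * np.log(p)).sum())
    if log_base is not None:
        h /= math.log(log_base)
    return h


def jaccard_distance(a, b, mode: JaccardMode = "binary") -> float:
    """Jaccard dissimilarity between two count vectors.

    ``binary`` compares presence sets: 1 - |A & B| / |A | B|.
    ``quantitative`` is 2B/(1+B) with B the Bray-Curtis dissimilarity on
    the raw counts.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("vectors differ in length")
    if mode == "quantitative":
        bc = bray_curtis(a, b)
        return 2.0 * bc / (1.0 + bc)
    pa, pb = a > 0, b > 0
    union = int((pa | pb).sum())
    if union == 0:
        raise ValidationError("Jaccard distance undefined for two all-zero vectors")
    inter = int((pa & pb).sum())
    return 1.0 - inter / union


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity sum|a_i - b_i| / sum(a_i + b_i)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("vectors differ in length")
    denom = float((a + b).sum())
    if denom == 0:
        raise ValidationError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(a - b).sum() / denom)


# ---------------------------------------------------------------------------
# Matrix-level operations
# ---------------------------------------------------------------------------


def _condensed(
    counts: pd.DataFrame, metric: Metric, mode: JaccardMode
) -> np.ndarray:
    arr = counts.to_numpy(dtype=float)
    if (arr.sum(axis=1) == 0).any():
        sid = counts.index[arr.sum(axis=1) == 0][0]
        raise ValidationError(f"sample {sid!r} has zero reads; distances undefined")
    if metric == "braycurtis" or (metric == "jaccard" and mode == "quantitative"):
        d = pdist(arr, metric="braycurtis")
        if metric == "jaccard":
            d = 2.0 * d / (1.0 + d)
    else:
        d = pdist(arr > 0, metric="jaccard")
    return d


def pairwise_distances(
    table: GenusCountTable,
    metric: Metric = "jaccard",
    mode: JaccardMode = "binary",
) -> DistanceMatrix:
    """All pairwise sample distances for the chosen metric, as a
    labelled, symmetric, hollow distance matrix."""
    if table.n_samples < 2:
        raise ValidationError("need at least 2 samples for pairwise distances")
    d = _condensed(table.counts, metric, mode)
    return DistanceMatrix(squareform(d), ids=[str(i) for i in table.sample_ids])


# ---------------------------------------------------------------------------
# Alpha diversity and uniqueness summaries
# ---------------------------------------------------------------------------


@dataclass
class AlphaTable:
    """Per-sample observed richness and Shannon diversity."""

    table: pd.DataFrame  # index sample_id; columns observed, shannon

    def medians(self) -> dict[str, float]:
        return {
            "observed": float(self.table["observed"].median()),
            "shannon": float(self.table["shannon"].median()),
        }

    def write(self, path) -> None:
        out = self.table.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


def alpha_table(table: GenusCountTable, log_base: float | None = None) -> AlphaTable:
    arr = table.counts.to_numpy(dtype=float)
    observed = (arr > 0).sum(axis=1)
    totals = arr.sum(axis=1)
    if (totals == 0).any():
        sid = table.sample_ids[totals == 0][0]
        raise ValidationError(f"sample {sid!r} has zero reads; Shannon undefined")
    p = arr / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=1)
    if log_base is not None:
        h = h / math.log(log_base)
    frame = pd.DataFrame(
        {"observed": observed.astype(int), "shannon": h}, index=table.sample_ids
    )
    return AlphaTable(table=frame)


@dataclass
class UniquenessSummary:
    """Distribution of within-country pairwise distances."""

    country: str
    n_samples: int
    n_pairs: int
    median_distance: float
    distances: np.ndarray  # condensed upper triangle

    def __post_init__(self) -> None:
        if self.n_pairs != self.n_samples * (self.n_samples - 1) // 2:
            raise ValidationError(f"{self.country}: pair count inconsistent")


def country_uniqueness(
    table: GenusCountTable,
    metric: Metric = "jaccard",
    mode: JaccardMode = "binary",
) -> list[UniquenessSummary]:
    """Median pairwise distance among each country's samples.

    Countries with fewer than two samples have no pairs and are skipped
    with a warning.
    """
    summaries = []
    for country, group in table.sample_meta.groupby("country", sort=True):
        ids = group.index
        if len(ids) < 2:
            logger.warning("country %s has %d sample(s); skipped", country, len(ids))
            continue
        d = _condensed(table.counts.loc[ids], metric, mode)
        summaries.append(
            UniquenessSummary(
                country=str(country),
                n_samples=len(ids),
                n_pairs=len(d),
                median_distance=float(np.median(d)),
                distances=d,
            )
        )
    if not summaries:
        logger.warning("no country has >= 2 samples; uniqueness summary empty")
    return summaries


def aggregate_to_phylum(table: GenusCountTable) -> GenusCountTable:
    """Collapse taxa by phylum label, summing counts.

    Each sample's read total is conserved exactly; the unclassified
    sentinel becomes its own group.  The output taxon ids are the phylum
    labels themselves.
    """
    phyla = table.taxon_meta["phylum"]
    collapsed = table.counts.T.groupby(phyla).sum().T
    taxon_meta = pd.DataFrame(
        {"genus": collapsed.columns, "phylum": collapsed.columns},
        index=pd.Index(collapsed.columns, name="taxon_id"),
    )
    return GenusCountTable(
        counts=collapsed.astype(np.int64),
        sample_meta=table.sample_meta.copy(),
        taxon_meta=taxon_meta,
    )


def relative_abundance(table: GenusCountTable) -> pd.DataFrame:
    """Row-normalised counts (each sample sums to 1)."""
    totals = table.counts.sum(axis=1).astype(float)
    if (totals == 0).any():
        raise ValidationError("all-zero sample; relative abundance undefined")
    return table.counts.div(totals, axis=0)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices over the same ids.

    r is the Pearson correlation of the off-diagonal upper triangles; the
    one-sided p-value counts joint row/column permutations of ``d2`` with
    r* >= r, using the add-one estimator (1 + hits) / (1 + n_perm).  With
    ``exhaustive=True`` all n! permutations are enumerated (n <= 8) and
    the exact p = #{r* >= r} / n! is returned.
    """
    if list(d1.ids) != list(d2.ids):
        raise ValidationError("distance matrices have different ids or ordering")
    n = d1.shape[0]
    if n < 3:
        raise ValidationError("Mantel test needs at least 3 objects")
    x = _upper(d1.data)
    y = _upper(d2.data)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero-variance distance triangle; r undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])

    mat2 = d2.data
    if exhaustive:
        if n > 8:
            raise ValidationError("exhaustive enumeration limited to n <= 8")
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            idx = np.asarray(perm)
            r_star = float(np.corrcoef(x, _upper(mat2[np.ix_(idx, idx)]))[0, 1])
            hits += r_star >= r_obs - 1e-12
            total += 1
        return r_obs, hits / total

    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        r_star = float(np.corrcoef(x, _upper(mat2[np.ix_(idx, idx)]))[0, 1])
        hits += r_star >= r_obs - 1e-12
    p = (1 + hits) / (1 + n_perm)
    return r_obs, p
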