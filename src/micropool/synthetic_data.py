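"""Synthetic multi-project, multi-country genus archives with known truth.

The generator emulates the statistical shape of a continental amplicon
archive: ~33 bioprojects spread over 9 of 13 South American countries,
project sizes between 9 and 881 samples, per-sample read depths with a
median near 3.37e4, a long lognormal tail of genus abundances, a slice of
phylum-unclassified reads, and planted low-depth samples and rare taxa so
the downstream filter cascade has real work to do.

Generative model, per sample: the country's taxon pool is the continental
core plus country-private and shared regional taxa; each pool taxon enters
the sample's support by an independent Bernoulli draw (the retention
probability is the country's heterogeneity knob — lower retention means
fewer shared taxa between compatriots and thus higher within-country
Jaccard distances); reads are then allocated multinomially over the
support with lognormal propensities.  Absence therefore arises from pool
membership and sampling, with no explicit zero-inflation parameter.

Planted entities are constructed so that, by margin, they are exactly
what the default filter cascade removes:

* low-depth samples draw depths in [1000, 9500] (< 10,000) while all
  other samples are floored at 12,000 reads;
* rare taxa carry either < 80 reads in total or occupy at most 2 samples,
  are added on top of the multinomial allocation, and are never placed in
  low-depth samples (so removing them cannot drag a surviving sample
  below the depth floor);
* high-unclassified samples have their phylum-unclassified propensity
  share pinned in [0.15, 0.35] versus 0.03 elsewhere, far from the 10%
  boundary on either side.

Abundant taxa whose lognormal draw is so small that they fall under the
read/prevalence thresholds anyway are re-derived from the emitted counts
at generation time and recorded in the ground truth alongside the planted
sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import (
    UNCLASSIFIED_PHYLUM,
    GenusCountTable,
    PopulationTable,
    ValidationError,
    get_logger,
    write_count_table,
    write_population_table,
)
from .project_qc import ReadTrackingTable

__all__ = [
    "SOUTH_AMERICAN_COUNTRIES",
    "SimulationConfig",
    "GroundTruth",
    "generate_archive",
    "make_population_table",
    "write_archive",
]

logger = get_logger(__name__)

SOUTH_AMERICAN_COUNTRIES = (
    "Argentina",
    "Bolivia",
    "Brazil",
    "Chile",
    "Colombia",
    "Ecuador",
    "French Guiana",
    "Guyana",
    "Paraguay",
    "Peru",
    "Suriname",
    "Uruguay",
    "Venezuela",
)

_PHYLA = (
    "Bacillota",
    "Bacteroidota",
    "Pseudomonadota",
    "Actinomycetota",
    "Verrucomicrobiota",
    "Fusobacteriota",
    "Desulfobacterota",
    "Cyanobacteria",
    "Spirochaetota",
)
_PHYLUM_WEIGHTS = (0.35, 0.25, 0.12, 0.10, 0.05, 0.04, 0.04, 0.03, 0.02)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic archive; defaults mirror the published shape."""

    seed: int = 0
    n_countries: int = 9
    n_projects: int = 33
    samples_per_project: tuple[int, int] = (9, 881)
    project_size_log_mean: float = float(np.log(60.0))
    project_size_log_sd: float = 1.0
    continental_taxon_pool_size: int = 2246
    core_taxon_fraction: float = 0.35  # of the abundant (non-rare) pool
    country_private_taxa: int = 25
    taxon_log_abundance_mean: float = 0.0
    taxon_log_abundance_sd: float = 3.0
    sample_depth_log_mean: float = float(np.log(3.37e4))  # median ~33,700 reads
    sample_depth_log_sd: float = 0.5
    normal_depth_floor: int = 12_000  # keeps non-planted samples clear of 10,000
    frac_low_depth_samples: float = 0.045
    low_depth_range: tuple[int, int] = (1_000, 9_500)
    frac_unclassified_phylum_taxa: float = 0.08
    target_unclassified_share: float = 0.03
    frac_high_unclassified_samples: float = 0.02
    high_unclassified_range: tuple[float, float] = (0.15, 0.35)
    rare_taxon_fraction: float = 0.50
    core_retention: float = 0.35
    country_retention_range: tuple[float, float] = (0.10, 0.40)
    setting_mix: tuple[float, float] = (0.55, 0.35)  # industrialised, non-ind.
    disease_project_fraction: float = 0.5
    chimeric_fraction_range: tuple[float, float] = (0.02, 0.15)
    qc_fail_project_fraction: float = 0.0

    def validate(self) -> None:
        fracs = {
            "core_taxon_fraction": self.core_taxon_fraction,
            "frac_low_depth_samples": self.frac_low_depth_samples,
            "frac_unclassified_phylum_taxa": self.frac_unclassified_phylum_taxa,
            "target_unclassified_share": self.target_unclassified_share,
            "frac_high_unclassified_samples": self.frac_high_unclassified_samples,
            "rare_taxon_fraction": self.rare_taxon_fraction,
            "core_retention": self.core_retention,
            "disease_project_fraction": self.disease_project_fraction,
            "qc_fail_project_fraction": self.qc_fail_project_fraction,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name}={value} outside [0, 1]")
        if sum(self.setting_mix) > 1.0:
            raise ValidationError("setting_mix fractions exceed 1")
        if not 1 <= self.n_countries <= len(SOUTH_AMERICAN_COUNTRIES):
            raise ValidationError(
                f"n_countries must be in [1, {len(SOUTH_AMERICAN_COUNTRIES)}]"
            )
        if self.n_projects < self.n_countries:
            raise ValidationError("need at least one project per country")
        lo, hi = self.samples_per_project
        if lo < 1 or hi < lo:
            raise ValidationError("invalid samples_per_project range")
        n_rare = int(round(self.rare_taxon_fraction * self.continental_taxon_pool_size))
        n_abundant = self.continental_taxon_pool_size - n_rare
        needed = (
            int(round(self.core_taxon_fraction * n_abundant))
            + self.n_countries * self.country_private_taxa
        )
        if needed > n_abundant:
            raise ValidationError(
                f"taxon pool too small: core + private needs {needed} abundant "
                f"taxa but only {n_abundant} exist"
            )
        if self.low_depth_range[1] >= 10_000:
            raise ValidationError("low-depth range must stay below 10,000 reads")
        if self.normal_depth_floor <= 10_000:
            raise ValidationError("normal depth floor must exceed 10,000 reads")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    n_samples: int
    n_taxa: int
    per_country_richness: dict[str, int]
    continental_richness: int
    occupancy: pd.Series  # taxa with occupancy > 0 over all samples
    low_depth_samples: list[str]
    high_unclassified_samples: list[str]
    rare_taxa: list[str]
    removed_taxa_low_reads: list[str]
    removed_taxa_low_prevalence: list[str]
    removed_recheck_samples: list[str]
    removed_unclassified_samples: list[str]
    expected_filtered_shape: tuple[int, int]
    country_retention: dict[str, float]
    qc_fail_projects: list[str]
    project_countries: dict[str, str] = field(default_factory=dict)


def _derive_filter_truth(
    counts: pd.DataFrame,
    unclassified: np.ndarray,
    low_depth: list[str],
    high_unclassified: list[str],
    rare_taxa: list[str],
) -> dict:
    """Re-derive the filter-cascade outcome from the raw thresholds.

    Works directly on column/row sums (not via the cascade code) so the
    closed-loop tests compare two independent routes to the same sets.
    Planted entities must fall on their planted side of the thresholds
    (anything else is a generation bug and raises); the depth re-check and
    the unclassified-fraction stage are re-derived rather than assumed,
    because removing a stray high-count low-prevalence taxon can
    legitimately drag a surviving sample back below the depth floor.
    """
    arr = counts.to_numpy()
    row_sums = arr.sum(axis=1)
    stage1_removed = set(counts.index[row_sums < 10_000])
    if stage1_removed != set(low_depth):
        raise ValidationError("planted low-depth samples drifted across the threshold")
    keep_rows = row_sums >= 10_000

    # taxa never observed in any sample do not enter the consolidated
    # archive at all, so they are not "removed" by any filter stage
    observed = arr.sum(axis=0) > 0
    col_sums = arr[keep_rows].sum(axis=0)
    low_reads = observed & (col_sums < 80)
    prevalence = (arr[keep_rows] > 0).sum(axis=0)
    low_prev = observed & (~low_reads) & (prevalence < 3)
    removed_low_reads = [str(t) for t in counts.columns[low_reads]]
    removed_low_prev = [str(t) for t in counts.columns[low_prev]]
    observed_rare = set(rare_taxa) & set(counts.columns[observed])
    if not observed_rare <= set(removed_low_reads) | set(removed_low_prev):
        raise ValidationError("a planted rare taxon survived the thresholds")

    keep_cols = observed & ~(low_reads | low_prev)
    sub = arr[np.ix_(keep_rows, keep_cols)]
    kept_ids = counts.index[keep_rows]
    resum = sub.sum(axis=1)
    recheck_removed = [str(s) for s in kept_ids[resum < 10_000]]
    keep2 = resum >= 10_000

    uncl_cols = unclassified[keep_cols]
    sub2 = sub[keep2]
    frac = sub2[:, uncl_cols].sum(axis=1) / sub2.sum(axis=1)
    stage5_removed = [str(s) for s in kept_ids[keep2][frac > 0.10]]
    if not set(high_unclassified) <= set(recheck_removed) | set(stage5_removed):
        raise ValidationError(
            "a planted high-unclassified sample survived the thresholds"
        )
    shape = (
        int(keep2.sum()) - len(stage5_removed),
        int(keep_cols.sum()),
    )
    return {
        "removed_taxa_low_reads": removed_low_reads,
        "removed_taxa_low_prevalence": removed_low_prev,
        "removed_recheck_samples": recheck_removed,
        "removed_unclassified_samples": stage5_removed,
        "expected_filtered_shape": shape,
    }


def generate_archive(
    config: SimulationConfig,
) -> tuple[list[GenusCountTable], list[ReadTrackingTable], GroundTruth]:
    """Generate per-project tables, tracking tables and the ground truth.

    Fully reproducible from ``config.seed``; running twice yields
    identical objects.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # -- taxon pool --------------------------------------------------------
    n_pool = config.continental_taxon_pool_size
    n_rare = int(round(config.rare_taxon_fraction * n_pool))
    n_abundant = n_pool - n_rare
    taxon_ids = np.array([f"t{i:04d}" for i in range(n_pool)])
    phyla = rng.choice(_PHYLA, size=n_pool, p=_PHYLUM_WEIGHTS)
    uncl_mask = rng.random(n_pool) < config.frac_unclassified_phylum_taxa
    phyla = np.where(uncl_mask, UNCLASSIFIED_PHYLUM, phyla)
    taxon_meta = pd.DataFrame(
        {"genus": [f"g{i:04d}" for i in range(n_pool)], "phylum": phyla},
        index=pd.Index(taxon_ids, name="taxon_id"),
    )

    abundant = np.arange(n_abundant)
    rare = np.arange(n_abundant, n_pool)
    n_core = int(round(config.core_taxon_fraction * n_abundant))
    core = abundant[:n_core]

    countries = list(
        rng.choice(SOUTH_AMERICAN_COUNTRIES, size=config.n_countries, replace=False)
    )
    pools: dict[str, np.ndarray] = {}
    cursor = n_core
    for country in countries:
        private = abundant[cursor : cursor + config.country_private_taxa]
        cursor += config.country_private_taxa
        pools[country] = private
    # remaining abundant taxa shared by a random subset of >= 2 countries
    for t in abundant[cursor:]:
        k = int(rng.integers(2, config.n_countries + 1)) if config.n_countries > 1 else 1
        chosen = rng.choice(config.n_countries, size=k, replace=False)
        for ci in chosen:
            pools[countries[ci]] = np.append(pools[countries[ci]], t)
    pools = {c: np.concatenate([core, np.sort(p)]) for c, p in pools.items()}

    propensity = np.exp(
        rng.normal(
            config.taxon_log_abundance_mean,
            config.taxon_log_abundance_sd,
            size=n_abundant,
        )
    )
    retention = {
        c: float(rng.uniform(*config.country_retention_range)) for c in countries
    }

    # -- projects ----------------------------------------------------------
    project_ids = [f"P{i:03d}" for i in range(config.n_projects)]
    project_country = {}
    for i, pid in enumerate(project_ids):
        if i < config.n_countries:
            project_country[pid] = countries[i]
        else:
            project_country[pid] = countries[int(rng.integers(config.n_countries))]
    sizes = np.clip(
        np.round(
            rng.lognormal(
                config.project_size_log_mean,
                config.project_size_log_sd,
                size=config.n_projects,
            )
        ).astype(int),
        *config.samples_per_project,
    )
    p_ind, p_non = config.setting_mix
    settings = {}
    disease = {}
    for pid in project_ids:
        u = rng.random()
        if u < p_ind:
            settings[pid] = "industrialised"
        elif u < p_ind + p_non:
            settings[pid] = "non_industrialised"
        else:
            settings[pid] = "unknown"
        disease[pid] = (
            settings[pid] == "non_industrialised"
            and rng.random() < config.disease_project_fraction
        )
    layouts = {
        pid: ("paired" if rng.random() < 0.8 else "single") for pid in project_ids
    }
    qc_fail = {
        pid: rng.random() < config.qc_fail_project_fraction for pid in project_ids
    }

    # -- samples -----------------------------------------------------------
    n_samples = int(sizes.sum())
    counts = np.zeros((n_samples, n_pool), dtype=np.int64)
    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    low_depth: list[str] = []
    high_unclassified: list[str] = []
    uncl_flags = phyla == UNCLASSIFIED_PHYLUM

    row = 0
    for pid, size in zip(project_ids, sizes):
        country = project_country[pid]
        pool = pools[country]
        pool_uncl = uncl_flags[pool]
        keep_core = np.isin(pool, core)
        for _ in range(size):
            sid = f"s{row:05d}"
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "project_id": pid,
                    "country": country,
                    "setting": settings[pid],
                    "library_layout": layouts[pid],
                    "disease_context": "disease" if disease[pid] else "none",
                }
            )
            u = rng.random()
            if u < config.frac_low_depth_samples:
                kind = "low"
                low_depth.append(sid)
            elif u < config.frac_low_depth_samples + config.frac_high_unclassified_samples:
                kind = "high_uncl"
                high_unclassified.append(sid)
            else:
                kind = "normal"

            keep_p = np.where(keep_core, config.core_retention, retention[country])
            support = pool[rng.random(len(pool)) < keep_p]
            if support.size == 0:
                support = pool[keep_core][:1]
            weights = propensity[support].copy()
            sup_uncl = uncl_flags[support]
            if kind == "high_uncl":
                target = float(rng.uniform(*config.high_unclassified_range))
            else:
                target = config.target_unclassified_share
            if not sup_uncl.any():
                # force one unclassified pool taxon in so the share is pinnable
                extra_pool = pool[pool_uncl]
                if extra_pool.size:
                    extra = extra_pool[np.argmax(propensity[extra_pool])]
                    support = np.append(support, extra)
                    weights = np.append(weights, propensity[extra])
                    sup_uncl = np.append(sup_uncl, True)
            if sup_uncl.any() and not sup_uncl.all():
                w_u = weights[sup_uncl].sum()
                w_c = weights[~sup_uncl].sum()
                weights[sup_uncl] *= target * w_c / ((1.0 - target) * w_u)

            if kind == "low":
                depth = int(rng.integers(*config.low_depth_range))
            else:
                depth = int(
                    max(
                        config.normal_depth_floor,
                        round(
                            rng.lognormal(
                                config.sample_depth_log_mean,
                                config.sample_depth_log_sd,
                            )
                        ),
                    )
                )
            counts[row, support] = rng.multinomial(depth, weights / weights.sum())
            row += 1

    sample_meta = pd.DataFrame(meta_rows).set_index("sample_id")
    sample_index = pd.Index(sample_ids, name="sample_id")

    # -- planted rare taxa (never in low-depth samples) --------------------
    low_set = set(low_depth)
    normal_rows = np.array(
        [i for i, s in enumerate(sample_ids) if s not in low_set], dtype=np.int64
    )
    country_of_row = sample_meta["country"].to_numpy()
    for t in rare:
        country = countries[int(rng.integers(config.n_countries))]
        hosts_pool = normal_rows[country_of_row[normal_rows] == country]
        if hosts_pool.size == 0:
            hosts_pool = normal_rows
        if hosts_pool.size == 0:
            continue  # degenerate config: nowhere safe to plant this taxon
        # ~89% of rare taxa fail on total reads, the rest on prevalence,
        # mirroring the roughly 50%-then-12% removal split of real archives
        if rng.random() < 0.89:
            # low total reads (< 80), any prevalence up to 5
            total = int(rng.integers(1, 80))
            k = int(min(rng.integers(1, 6), hosts_pool.size, total))
            hosts = rng.choice(hosts_pool, size=k, replace=False)
            alloc = rng.multinomial(total - k, np.full(k, 1.0 / k)) + 1
        else:
            # low prevalence (<= 2 samples), reads possibly >= 80
            k = int(min(rng.integers(1, 3), hosts_pool.size))
            hosts = rng.choice(hosts_pool, size=k, replace=False)
            alloc = rng.integers(40, 250, size=k)
        counts[hosts, t] = alloc

    counts_frame = pd.DataFrame(counts, index=sample_index, columns=taxon_ids)

    # -- ground truth ------------------------------------------------------
    occupancy = pd.Series((counts > 0).sum(axis=0), index=taxon_ids)
    occupancy = occupancy[occupancy > 0]
    per_country = {}
    for country in countries:
        rows = country_of_row == country
        per_country[country] = int(((counts[rows] > 0).any(axis=0)).sum())
    derived = _derive_filter_truth(
        counts_frame,
        uncl_flags,
        low_depth,
        high_unclassified,
        [str(t) for t in taxon_ids[rare]],
    )
    truth = GroundTruth(
        n_samples=n_samples,
        n_taxa=n_pool,
        per_country_richness=per_country,
        continental_richness=int(len(occupancy)),
        occupancy=occupancy,
        low_depth_samples=low_depth,
        high_unclassified_samples=high_unclassified,
        rare_taxa=[str(t) for t in taxon_ids[rare]],
        country_retention=retention,
        **derived,
        qc_fail_projects=[p for p, f in qc_fail.items() if f],
        project_countries=dict(project_country),
    )

    # -- split into per-project tables -------------------------------------
    tables = []
    for pid in project_ids:
        rows_mask = sample_meta["project_id"] == pid
        sub = counts_frame.loc[rows_mask.to_numpy()]
        observed = sub.columns[(sub > 0).any(axis=0)]
        tables.append(
            GenusCountTable(
                counts=sub[observed].copy(),
                sample_meta=sample_meta.loc[sub.index].copy(),
                taxon_meta=taxon_meta.loc[observed].copy(),
            )
        )

    # -- tracking tables (independent of count tables) ---------------------
    tracking = []
    for pid, size in zip(project_ids, sizes):
        n = int(size)
        input_reads = rng.integers(30_000, 80_000, size=n)
        prechimera = np.round(input_reads * rng.uniform(0.85, 0.98, size=n)).astype(
            np.int64
        )
        if qc_fail[pid]:
            chim = rng.uniform(0.45, 0.70, size=n)
        else:
            chim = rng.uniform(*config.chimeric_fraction_range, size=n)
        nonchimeric = np.floor(prechimera * (1.0 - chim)).astype(np.int64)
        sids = sample_meta.index[sample_meta["project_id"] == pid]
        tracking.append(
            ReadTrackingTable(
                project_id=pid,
                samples=pd.DataFrame(
                    {
                        "sample_id": list(sids),
                        "input_reads": input_reads,
                        "prechimera_reads": prechimera,
                        "nonchimeric_reads": nonchimeric,
                    }
                ),
            )
        )

    return tables, tracking, truth


def make_population_table(
    config: SimulationConfig,
    skew: float = 1.0,
    base_population: int = 10_000_000,
    reference_year: int = 2022,
) -> PopulationTable:
    """Synthetic regional population table covering all 13 countries.

    Populations follow ``base * (rank + 1) ** skew`` over the country
    list, so ``skew=0`` gives equal populations and larger skews plant
    over/under-representation relative to uniform sampling.
    """
    pops = [
        int(round(base_population * (i + 1) ** skew))
        for i in range(len(SOUTH_AMERICAN_COUNTRIES))
    ]
    table = pd.DataFrame(
        {"population": pops},
        index=pd.Index(SOUTH_AMERICAN_COUNTRIES, name="country"),
    )
    return PopulationTable(table=table, reference_year=reference_year)


def write_archive(
    tables: Sequence[GenusCountTable],
    tracking: Sequence[ReadTrackingTable],
    truth: GroundTruth,
    populations: PopulationTable,
    out_dir: str | Path,
) -> None:
    """Emit per-project TSVs, one tracking TSV, a population TSV and a
    ground-truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for table in tables:
        pid = table.sample_meta["project_id"].iloc[0]
        write_count_table(
            table,
            out / f"{pid}_counts.tsv",
            out / f"{pid}_sample_meta.tsv",
            out / f"{pid}_taxon_meta.tsv",
        )
    rows = []
    for t in tracking:
        frame = t.samples.copy()
        frame.insert(0, "project_id", t.project_id)
        rows.append(frame)
    pd.concat(rows).to_csv(out / "tracking.tsv", sep="\t", index=False)
    write_population_table(populations, out / "population.tsv")
    manifest = pd.DataFrame(
        {
            "country": list(truth.per_country_richness),
            "true_richness": list(truth.per_country_richness.values()),
            "retention": [
                truth.country_retention[c] for c in truth.per_country_richness
            ],
        }
    )
    manifest.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
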