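"""Core containers and plumbing for genus-level microbiome archives.

The central object is :class:`GenusCountTable`: an integer count matrix of
samples (rows) by genus-level taxa (columns), carrying per-sample metadata
(source project, country, industrialisation setting, library layout) and
per-taxon metadata (genus and phylum labels).  Everything downstream —
QC, the filter cascade, diversity, representation and accumulation
analysis — consumes and produces this object or plain TSV serialisations
of it.

All tables are TSV (UTF-8, tab-delimited).  Validation is strict: a table
violating an invariant raises :class:`ValidationError` and is never
silently repaired.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "UNKNOWN",
    "UNCLASSIFIED_PHYLUM",
    "SETTINGS",
    "LIBRARY_LAYOUTS",
    "ValidationError",
    "ParseError",
    "GenusCountTable",
    "PopulationTable",
    "read_count_table",
    "write_count_table",
    "read_population_table",
    "write_population_table",
    "load_config",
    "get_logger",
]

#: Sentinel for any unknown metadata value (never an empty cell).
UNKNOWN = "unknown"

#: Phylum label marking reads unclassified at the phylum level.
UNCLASSIFIED_PHYLUM = "unclassified_phylum"

SETTINGS = frozenset({"industrialised", "non_industrialised", UNKNOWN})
LIBRARY_LAYOUTS = frozenset({"paired", "single", UNKNOWN})

SAMPLE_META_COLUMNS = ("project_id", "country", "setting", "library_layout")
TAXON_META_COLUMNS = ("genus", "phylum")


class ValidationError(ValueError):
    """A table violates one of its structural invariants."""


class ParseError(ValueError):
    """A file on disk could not be interpreted as the expected table."""


def get_logger(name: str = "micropool") -> logging.Logger:
    """Package logger; handlers are configured once, at first use."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


logger = get_logger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenusCountTable:
    """Samples x taxa integer count matrix with sample and taxon metadata.

    Parameters
    ----------
    counts:
        DataFrame of non-negative integers; index = sample ids,
        columns = taxon ids.
    sample_meta:
        DataFrame indexed by sample id with columns
        ``project_id, country, setting, library_layout``.
    taxon_meta:
        DataFrame indexed by taxon id with columns ``genus, phylum``.

    Metadata frames must cover exactly the samples/taxa present in
    ``counts``; on construction they are aligned to the counts ordering.
    Country validity against a population table is checked downstream
    (where a :class:`PopulationTable` is in scope), not here.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    taxon_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()
        # align metadata row order to the count matrix (set equality was
        # checked in validate; ordering is presentation, not content)
        self.sample_meta = self.sample_meta.loc[self.counts.index]
        self.taxon_meta = self.taxon_meta.loc[self.counts.columns]
        self.sample_meta.index.name = "sample_id"
        self.taxon_meta.index.name = "taxon_id"

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()][0]
            raise ValidationError(f"duplicate sample_id {dup!r} in count table")
        if c.columns.has_duplicates:
            dup = c.columns[c.columns.duplicated()][0]
            raise ValidationError(f"duplicate taxon_id {dup!r} in count table")
        if len(c.columns):
            arr = c.to_numpy()
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.issubdtype(arr.dtype, np.number):
                    raise ValidationError("count table contains non-numeric values")
                if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                    raise ValidationError("count table contains non-integer values")
            if (arr < 0).any():
                i, j = np.argwhere(arr < 0)[0]
                raise ValidationError(
                    f"negative count at sample {c.index[i]!r}, taxon {c.columns[j]!r}"
                )
        for kind, meta, ids, cols in (
            ("sample", self.sample_meta, c.index, SAMPLE_META_COLUMNS),
            ("taxon", self.taxon_meta, c.columns, TAXON_META_COLUMNS),
        ):
            missing_cols = set(cols) - set(meta.columns)
            if missing_cols:
                raise ValidationError(
                    f"{kind} metadata missing columns {sorted(missing_cols)}"
                )
            if meta.index.has_duplicates:
                dup = meta.index[meta.index.duplicated()][0]
                raise ValidationError(f"duplicate {kind}_id {dup!r} in metadata")
            only_counts = set(ids) - set(meta.index)
            if only_counts:
                raise ValidationError(
                    f"{kind}_id {sorted(only_counts)[0]!r} has counts but no metadata"
                )
            only_meta = set(meta.index) - set(ids)
            if only_meta:
                raise ValidationError(
                    f"{kind}_id {sorted(only_meta)[0]!r} has metadata but no counts"
                )
        bad_setting = set(self.sample_meta["setting"]) - SETTINGS
        if bad_setting:
            raise ValidationError(f"unrecognised setting {sorted(bad_setting)[0]!r}")
        bad_layout = set(self.sample_meta["library_layout"]) - LIBRARY_LAYOUTS
        if bad_layout:
            raise ValidationError(
                f"unrecognised library_layout {sorted(bad_layout)[0]!r}"
            )

    # -- convenience --------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def taxon_ids(self) -> pd.Index:
        return self.counts.columns

    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def subset(
        self,
        samples: Iterable[str] | None = None,
        taxa: Iterable[str] | None = None,
    ) -> "GenusCountTable":
        """Restrict to the given samples and/or taxa (order preserved)."""
        counts = self.counts
        if samples is not None:
            counts = counts.loc[list(samples)]
        if taxa is not None:
            counts = counts[list(taxa)]
        return GenusCountTable(
            counts=counts.copy(),
            sample_meta=self.sample_meta.loc[counts.index].copy(),
            taxon_meta=self.taxon_meta.loc[counts.columns].copy(),
        )

    def equals(self, other: "GenusCountTable") -> bool:
        """Exact equality of counts and metadata (including ordering)."""
        return (
            self.counts.equals(other.counts)
            and self.sample_meta.equals(other.sample_meta)
            and self.taxon_meta.equals(other.taxon_meta)
        )


@dataclass
class PopulationTable:
    """Country populations for one reference year (World Bank style)."""

    table: pd.DataFrame  # index: country; column: population
    reference_year: int = 2022

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise ValidationError(f"duplicate country {dup!r} in population table")
        pops = t["population"].to_numpy()
        if not np.issubdtype(pops.dtype, np.integer) and np.any(
            pops != np.floor(pops)
        ):
            raise ValidationError("populations must be integers")
        if (pops <= 0).any():
            bad = t.index[pops <= 0][0]
            raise ValidationError(f"non-positive population for {bad!r}")

    @property
    def countries(self) -> pd.Index:
        return self.table.index

    def shares(self) -> pd.Series:
        """Each country's fraction of the total population (sums to 1)."""
        pops = self.table["population"].astype(float)
        return pops / pops.sum()


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, index_name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    frame.index.name = index_name
    frame.index = frame.index.astype(str)
    return frame


def read_count_table(
    counts_path: str | Path,
    sample_meta_path: str | Path,
    taxon_meta_path: str | Path,
    transpose: bool = False,
) -> GenusCountTable:
    """Read a count table plus its two metadata tables from TSV.

    The count file has samples as rows and taxa as columns (header row of
    taxon ids, first column sample ids); ``transpose=True`` accepts the
    transposed orientation (taxa as rows), which some deposited tables use.
    """
    raw = _read_tsv(counts_path, "sample_id")
    if transpose:
        raw = raw.T
        raw.index.name = "sample_id"
    counts = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=np.int64)
    for col in raw.columns:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna() | (numeric != np.floor(numeric.fillna(0)))
        if bad.any():
            row = raw.index[bad][0]
            raise ParseError(
                f"non-integer count at sample {row!r}, taxon {col!r} "
                f"in {counts_path}"
            )
        if (numeric < 0).any():
            row = raw.index[numeric < 0][0]
            raise ParseError(
                f"negative count at sample {row!r}, taxon {col!r} in {counts_path}"
            )
        counts[col] = numeric.astype(np.int64)
    sample_meta = _read_tsv(sample_meta_path, "sample_id")
    taxon_meta = _read_tsv(taxon_meta_path, "taxon_id")
    return GenusCountTable(counts=counts, sample_meta=sample_meta, taxon_meta=taxon_meta)


def write_count_table(
    table: GenusCountTable,
    counts_path: str | Path,
    sample_meta_path: str | Path | None = None,
    taxon_meta_path: str | Path | None = None,
) -> None:
    """Write a table (and, when paths are given, its metadata) to TSV.

    Output is byte-stable for a fixed table: rows and columns are written
    in the table's own order. ``read_count_table`` inverts this exactly.
    """
    counts_path = Path(counts_path)
    counts_path.parent.mkdir(parents=True, exist_ok=True)
    out = table.counts.copy()
    out.index.name = "sample_id"
    out.to_csv(counts_path, sep="\t")
    if sample_meta_path is not None:
        meta = table.sample_meta.copy()
        meta.index.name = "sample_id"
        meta.to_csv(sample_meta_path, sep="\t")
    if taxon_meta_path is not None:
        meta = table.taxon_meta.copy()
        meta.index.name = "taxon_id"
        meta.to_csv(taxon_meta_path, sep="\t")


def read_population_table(path: str | Path) -> PopulationTable:
    """Read a population TSV with columns country, population, year."""
    frame = pd.read_csv(path, sep="\t", dtype={"country": str})
    required = {"country", "population", "year"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"population table missing columns {sorted(missing)}")
    years = frame["year"].unique()
    if len(years) != 1:
        raise ParseError(f"population table mixes reference years {sorted(years)}")
    table = frame.set_index("country")[["population"]].astype(np.int64)
    return PopulationTable(table=table, reference_year=int(years[0]))


def write_population_table(populations: PopulationTable, path: str | Path) -> None:
    frame = populations.table.reset_index()
    frame["year"] = populations.reference_year
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file into a plain dict."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ParseError(f"config {path} is not a mapping")
    return data
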