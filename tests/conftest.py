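"""Shared fixtures: hand-built toy tables and a small generated archive."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from micropool import GenusCountTable, SimulationConfig, generate_archive

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def build_table(
    counts,
    sample_ids=None,
    taxon_ids=None,
    countries=None,
    phyla=None,
    projects=None,
    settings_=None,
) -> GenusCountTable:
    """Assemble a GenusCountTable from a 2-D array and optional metadata."""
    arr = np.asarray(counts, dtype=np.int64)
    n, t = arr.shape
    sample_ids = list(sample_ids) if sample_ids is not None else [f"s{i}" for i in range(n)]
    taxon_ids = list(taxon_ids) if taxon_ids is not None else [f"t{j}" for j in range(t)]
    countries = list(countries) if countries is not None else ["Peru"] * n
    phyla = list(phyla) if phyla is not None else ["Bacillota"] * t
    projects = list(projects) if projects is not None else ["P0"] * n
    settings_ = list(settings_) if settings_ is not None else ["unknown"] * n
    return GenusCountTable(
        counts=pd.DataFrame(arr, index=pd.Index(sample_ids, name="sample_id"), columns=taxon_ids),
        sample_meta=pd.DataFrame(
            {
                "project_id": projects,
                "country": countries,
                "setting": settings_,
                "library_layout": ["paired"] * n,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        ),
        taxon_meta=pd.DataFrame(
            {"genus": [f"g_{t}" for t in taxon_ids], "phylum": phyla},
            index=pd.Index(taxon_ids, name="taxon_id"),
        ),
    )


def small_config(seed: int = 7, **overrides) -> SimulationConfig:
    """A fast archive: 3 countries, 6 projects, ~100 samples, 200 taxa."""
    params = dict(
        seed=seed,
        n_countries=3,
        n_projects=6,
        samples_per_project=(5, 60),
        project_size_log_mean=float(np.log(15.0)),
        project_size_log_sd=0.6,
        continental_taxon_pool_size=200,
        country_private_taxa=10,
        qc_fail_project_fraction=0.3,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def small_archive():
    """(tables, tracking, truth) for the small synthetic archive."""
    return generate_archive(small_config())


@pytest.fixture()
def toy_table() -> GenusCountTable:
    return build_table(
        [[5, 0, 1], [0, 3, 3], [2, 2, 2]],
        sample_ids=["a", "b", "c"],
        taxon_ids=["tA", "tB", "tC"],
    )
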