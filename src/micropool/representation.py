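"""Local Representation Index (LRI).

The LRI asks whether a country contributes microbiome samples to the
archive in proportion to its share of the regional population.  With
sample share s and population share q, the ratio rho = s / q maps to

    lri = rho        when rho >= 1   (overrepresented, or balanced at 1)
    lri = -1 / rho   when rho <  1   (underrepresented)

so a value of +3 means three times more samples than the population share
predicts, and -3 means sampling would have to triple to catch up.  No
value can fall strictly inside (-1, 1).  Raw values are reported (no
log10 transform).  Countries present in the population table but absent
from the archive contribute to the population denominator and are flagged
``no_data``.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .io_core import (
    UNKNOWN,
    GenusCountTable,
    PopulationTable,
    ValidationError,
    get_logger,
)

__all__ = ["local_representation_index", "samples_per_country"]

logger = get_logger(__name__)

_BALANCED_RTOL = 1e-12


def samples_per_country(
    table: GenusCountTable, include_unknown: bool = False
) -> pd.Series:
    """Archive sample counts per country from sample metadata.

    Samples with country "unknown" are dropped unless ``include_unknown``.
    """
    countries = table.sample_meta["country"]
    if not include_unknown:
        countries = countries[countries != UNKNOWN]
    return countries.value_counts().sort_index()


def local_representation_index(
    sample_counts: Mapping[str, int] | pd.Series,
    populations: PopulationTable,
) -> pd.DataFrame:
    """Compute the LRI table from per-country sample counts.

    Population shares are taken over every country in the population
    table (the regional denominator); sample shares over the supplied
    counts.  A country with samples but no population entry is an error;
    a country with population but no samples gets status ``no_data`` and
    an undefined (NaN) lri.

    Returns a DataFrame indexed by country with columns
    ``n_samples, population_share, sample_share, lri, status``.
    """
    counts = pd.Series(sample_counts, dtype=float)
    counts = counts[counts > 0]
    if counts.empty:
        raise ValidationError("no country has any samples")
    missing = set(counts.index) - set(populations.countries)
    if missing:
        raise ValidationError(
            f"country {sorted(missing)[0]!r} has samples but no population entry"
        )

    pop_share = populations.shares()
    sample_share = (counts / counts.sum()).reindex(pop_share.index, fill_value=0.0)

    rho = sample_share / pop_share
    lri = pd.Series(np.nan, index=pop_share.index)
    status = pd.Series("no_data", index=pop_share.index, dtype=object)
    has_data = sample_share > 0
    over = has_data & (rho >= 1.0)
    under = has_data & (rho < 1.0)
    lri[over] = rho[over]
    lri[under] = -1.0 / rho[under]
    status[over] = "overrepresented"
    status[under] = "underrepresented"
    balanced = has_data & np.isclose(rho, 1.0, rtol=_BALANCED_RTOL, atol=0.0)
    status[balanced] = "balanced"

    result = pd.DataFrame(
        {
            "n_samples": counts.reindex(pop_share.index, fill_value=0).astype(int),
            "population_share": pop_share,
            "sample_share": sample_share,
            "lri": lri,
            "status": status,
        }
    )
    result.index.name = "country"
    return result
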