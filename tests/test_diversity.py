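"""Alpha/beta diversity, uniqueness summaries, phylum aggregation, Mantel."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from skbio import DistanceMatrix
from skbio.diversity import beta_diversity
from skbio.stats.distance import mantel as skbio_mantel

from micropool import (
    ValidationError,
    aggregate_to_phylum,
    alpha_table,
    bray_curtis,
    country_uniqueness,
    jaccard_distance,
    mantel_test,
    observed_richness,
    pairwise_distances,
    relative_abundance,
    shannon,
)

from conftest import build_table


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------


def test_observed_richness():
    assert observed_richness([0, 0, 0]) == 0
    assert observed_richness([5, 0, 1, 2]) == 3


def test_shannon_known_values():
    assert shannon([10, 10, 10, 10]) == pytest.approx(math.log(4), abs=1e-12)
    assert shannon([42, 0, 0]) == 0.0
    # hand: p = (1/6, 1/3, 1/2) -> 1.01140
    assert shannon([1, 2, 3]) == pytest.approx(1.01140, abs=1e-4)
    assert shannon([1, 1], log_base=2) == pytest.approx(1.0)
    with pytest.raises(ValidationError):
        shannon([0, 0])


def test_jaccard_known_values():
    assert jaccard_distance([1, 1, 0], [2, 9, 0]) == 0.0
    assert jaccard_distance([1, 0], [0, 3]) == 1.0
    # presences {1,2,3} vs {2,3,4}: intersection 2, union 4
    assert jaccard_distance([1, 1, 1, 0], [0, 1, 1, 1]) == pytest.approx(0.5)
    with pytest.raises(ValidationError):
        jaccard_distance([0, 0], [0, 0])


def test_quantitative_jaccard_is_transformed_bray_curtis():
    a, b = [6, 2, 1], [2, 2, 0]
    bc = bray_curtis(a, b)
    assert jaccard_distance(a, b, mode="quantitative") == pytest.approx(
        2 * bc / (1 + bc)
    )


def test_bray_curtis_known_values():
    assert bray_curtis([3, 1], [3, 1]) == 0.0
    assert bray_curtis([5, 0], [0, 7]) == 1.0
    assert bray_curtis([6, 2], [2, 2]) == pytest.approx(4 / 12)
    with pytest.raises(ValidationError):
        bray_curtis([0], [0])


@given(
    st.lists(
        st.tuples(st.booleans(), st.booleans(), st.booleans()),
        min_size=3,
        max_size=12,
    )
)
def test_binary_jaccard_triangle_inequality(cols):
    a = np.array([c[0] for c in cols], dtype=int)
    b = np.array([c[1] for c in cols], dtype=int)
    c = np.array([c[2] for c in cols], dtype=int)
    if not (a.any() and b.any() and c.any()):
        return
    dab = jaccard_distance(a, b)
    dbc = jaccard_distance(b, c)
    dac = jaccard_distance(a, c)
    assert dac <= dab + dbc + 1e-12
    assert dab == jaccard_distance(b, a)  # symmetry


@given(
    st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=10).filter(
        lambda v: sum(v) > 0
    )
)
def test_shannon_bounded_by_log_richness(counts):
    s = observed_richness(counts)
    h = shannon(counts)
    assert -1e-9 <= h <= math.log(max(s, 1)) + 1e-9


# ---------------------------------------------------------------------------
# matrix level
# ---------------------------------------------------------------------------


def test_pairwise_matches_scalar_calls(toy_table):
    for metric, mode, scalar in [
        ("jaccard", "binary", jaccard_distance),
        ("braycurtis", "binary", bray_curtis),
        ("jaccard", "quantitative", lambda a, b: jaccard_distance(a, b, "quantitative")),
    ]:
        dm = pairwise_distances(toy_table, metric=metric, mode=mode)
        for i, j in itertools.combinations(range(3), 2):
            expected = scalar(
                toy_table.counts.iloc[i].to_numpy(), toy_table.counts.iloc[j].to_numpy()
            )
            assert dm.data[i, j] == pytest.approx(expected, abs=1e-12)


def test_pairwise_matches_reference_implementation(toy_table):
    ours = pairwise_distances(toy_table, metric="braycurtis")
    ref = beta_diversity(
        "braycurtis", toy_table.counts.to_numpy(), ids=list(toy_table.sample_ids)
    )
    np.testing.assert_allclose(ours.data, ref.data, atol=1e-12)


def test_pairwise_equivariant_under_sample_shuffle(toy_table):
    dm = pairwise_distances(toy_table)
    shuffled = toy_table.subset(samples=["c", "a", "b"])
    dm2 = pairwise_distances(shuffled)
    perm = [list(toy_table.sample_ids).index(s) for s in ["c", "a", "b"]]
    np.testing.assert_allclose(dm2.data, dm.data[np.ix_(perm, perm)])


def test_alpha_table_matches_scalars(toy_table):
    alpha = alpha_table(toy_table)
    for sid in toy_table.sample_ids:
        row = toy_table.counts.loc[sid].to_numpy()
        assert alpha.table.loc[sid, "observed"] == observed_richness(row)
        assert alpha.table.loc[sid, "shannon"] == pytest.approx(shannon(row))


def test_country_uniqueness_brute_force():
    table = build_table(
        [[1, 1, 0, 0], [0, 1, 1, 0], [1, 0, 1, 1], [2, 2, 0, 0], [2, 2, 0, 0]],
        countries=["Peru", "Peru", "Peru", "Chile", "Chile"],
    )
    summaries = {s.country: s for s in country_uniqueness(table)}
    peru = summaries["Peru"]
    rows = table.counts.iloc[:3].to_numpy()
    expected = sorted(
        jaccard_distance(rows[i], rows[j]) for i, j in itertools.combinations(range(3), 2)
    )
    assert peru.n_pairs == 3
    assert peru.median_distance == pytest.approx(expected[1])
    # identical samples: median 0
    assert summaries["Chile"].median_distance == 0.0


def test_country_with_single_sample_skipped(caplog):
    table = build_table([[1, 2], [2, 1]], countries=["Peru", "Chile"])
    with caplog.at_level("WARNING"):
        assert country_uniqueness(table) == []


def test_planted_heterogeneity_ranks_highest(small_archive):
    from micropool import consolidate_tables, filter_archive

    tables, _, truth = small_archive
    filtered, _ = filter_archive(consolidate_tables(tables))
    summaries = {s.country: s.median_distance for s in country_uniqueness(filtered)}
    # the country generated with the lowest taxon retention (most
    # heterogeneous) should not have the lowest median distance
    retention = truth.country_retention
    most_het = min(retention, key=retention.get)
    least_het = max(retention, key=retention.get)
    assert summaries[most_het] > summaries[least_het]


def test_aggregate_to_phylum_by_hand():
    table = build_table(
        [[1, 2, 3, 4], [5, 6, 7, 8]],
        phyla=["X", "X", "Y", "Y"],
    )
    out = aggregate_to_phylum(table)
    assert sorted(out.taxon_ids) == ["X", "Y"]
    assert out.counts.loc["s0", "X"] == 3 and out.counts.loc["s0", "Y"] == 7
    assert out.counts.loc["s1", "X"] == 11 and out.counts.loc["s1", "Y"] == 15
    # per-sample totals conserved
    assert (out.counts.sum(axis=1) == table.counts.sum(axis=1)).all()
    rel = relative_abundance(out)
    np.testing.assert_allclose(rel.sum(axis=1), 1.0)


def test_aggregate_conserves_reads_on_generated_table(small_archive):
    tables, _, _ = small_archive
    table = tables[0]
    out = aggregate_to_phylum(table)
    assert (out.counts.sum(axis=1) == table.counts.sum(axis=1)).all()


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------


def _random_dm(rng, n, ids):
    pts = rng.random((n, 2))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return DistanceMatrix(d, ids=ids)


def test_mantel_perfect_correlation():
    rng = np.random.default_rng(0)
    ids = list("abcde")
    d1 = _random_dm(rng, 5, ids)
    d2 = DistanceMatrix(2 * d1.data, ids=ids)
    r, p = mantel_test(d1, d2, n_perm=99, seed=1)
    assert r == pytest.approx(1.0)
    assert p <= 0.05


def test_mantel_exhaustive_matches_enumeration_oracle():
    rng = np.random.default_rng(3)
    ids = list("abcd")
    d1 = _random_dm(rng, 4, ids)
    d2 = _random_dm(rng, 4, ids)
    r, p = mantel_test(d1, d2, exhaustive=True)

    # independent enumeration over all 24 relabelings
    iu = np.triu_indices(4, 1)
    x = d1.data[iu]
    r_obs = np.corrcoef(x, d2.data[iu])[0, 1]
    hits = 0
    for perm in itertools.permutations(range(4)):
        permuted = d2.data[np.ix_(perm, perm)]
        hits += np.corrcoef(x, permuted[iu])[0, 1] >= r_obs - 1e-12
    assert r == pytest.approx(r_obs)
    assert p == pytest.approx(hits / 24)


def test_mantel_agrees_with_reference_implementation():
    rng = np.random.default_rng(5)
    ids = [f"s{i}" for i in range(8)]
    d1 = _random_dm(rng, 8, ids)
    d2 = _random_dm(rng, 8, ids)
    r, _ = mantel_test(d1, d2, n_perm=99, seed=0)
    r_ref, _, _ = skbio_mantel(d1, d2, method="pearson", permutations=0)
    assert r == pytest.approx(float(r_ref), abs=1e-12)


def test_mantel_errors():
    rng = np.random.default_rng(1)
    d1 = _random_dm(rng, 4, list("abcd"))
    d2 = _random_dm(rng, 4, list("abce"))
    with pytest.raises(ValidationError, match="ids"):
        mantel_test(d1, d2)
    flat = DistanceMatrix(1 - np.eye(4), ids=list("abcd"))
    with pytest.raises(ValidationError, match="variance"):
        mantel_test(flat, d1)
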