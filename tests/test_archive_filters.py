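"""Consolidation and the five-stage filter cascade."""

import numpy as np
import pandas as pd
import pytest

from micropool import (
    ValidationError,
    consolidate_tables,
    filter_archive,
)

from conftest import build_table


def test_single_table_consolidates_to_itself(toy_table):
    out = consolidate_tables([toy_table])
    assert out.counts.equals(toy_table.counts)
    assert out.total_reads() == toy_table.total_reads()


def test_union_of_taxa_with_zero_fill():
    t1 = build_table([[3, 1], [2, 4]], sample_ids=["s1", "s2"], taxon_ids=["A", "B"])
    t2 = build_table([[5, 6], [7, 8]], sample_ids=["s3", "s4"], taxon_ids=["B", "C"])
    out = consolidate_tables([t1, t2])
    assert set(out.taxon_ids) == {"A", "B", "C"}
    assert out.n_samples == 4
    # hand-computed column sums: A=5, B=1+4+5+7=17, C=6+8=14
    sums = out.counts.sum(axis=0)
    assert sums["A"] == 5 and sums["B"] == 17 and sums["C"] == 14
    assert out.counts.loc["s3", "A"] == 0  # zero-filled
    assert out.total_reads() == t1.total_reads() + t2.total_reads()


def test_duplicate_sample_across_projects_names_both(toy_table):
    other = build_table(
        [[1, 1, 1]], sample_ids=["a"], taxon_ids=["tA", "tB", "tC"], projects=["P9"]
    )
    with pytest.raises(ValidationError) as err:
        consolidate_tables([toy_table, other])
    assert "P0" in str(err.value) and "P9" in str(err.value)


def test_conflicting_taxon_metadata_rejected():
    t1 = build_table([[1]], sample_ids=["s1"], taxon_ids=["A"], phyla=["Bacillota"])
    t2 = build_table([[1]], sample_ids=["s2"], taxon_ids=["A"], phyla=["Bacteroidota"])
    with pytest.raises(ValidationError, match="conflicting"):
        consolidate_tables([t1, t2])


def test_consolidation_of_generated_projects(small_archive):
    tables, _, truth = small_archive
    out = consolidate_tables(tables)
    assert out.n_samples == sum(t.n_samples for t in tables) == truth.n_samples
    union = set()
    for t in tables:
        union |= set(t.taxon_ids)
    assert set(out.taxon_ids) == union
    assert out.total_reads() == sum(t.total_reads() for t in tables)


def test_fixed_point_table_unchanged():
    # 3 samples x 2 taxa, every threshold already satisfied
    table = build_table(
        np.full((3, 2), 6000), phyla=["Bacillota", "Bacteroidota"]
    )
    out, report = filter_archive(table)
    assert out.counts.equals(table.counts)
    assert all(s.n_removed == 0 for s in report.stages)
    report.validate()


def test_hand_traced_cascade():
    # thresholds 10 / 8 / 3 / 0.10; stage hits planted one per stage:
    # s6 (stage 1), A (stage 2), B (stage 3), s5 (stage 4), s4 (stage 5)
    counts = pd.DataFrame(
        [
            # A  B  C  D  E  F  G  H
            [1, 0, 5, 5, 5, 3, 2, 1],  # s1
            [0, 0, 5, 5, 5, 3, 3, 2],  # s2
            [0, 5, 4, 4, 4, 3, 2, 0],  # s3
            [0, 0, 5, 5, 5, 0, 2, 8],  # s4: unclassified frac 8/25 = 0.32
            [2, 4, 3, 2, 0, 0, 0, 0],  # s5: sum 11, drops to 5 after A,B removed
            [3, 0, 2, 0, 0, 0, 0, 0],  # s6: sum 5 < 10
        ],
        index=["s1", "s2", "s3", "s4", "s5", "s6"],
        columns=list("ABCDEFGH"),
    )
    table = build_table(
        counts.to_numpy(),
        sample_ids=counts.index,
        taxon_ids=counts.columns,
        phyla=["Bacillota"] * 7 + ["unclassified_phylum"],
    )
    out, report = filter_archive(
        table,
        min_sample_reads=10,
        min_taxon_reads=8,
        min_taxon_prevalence=3,
        max_unclassified_frac=0.10,
    )
    removed = {s.stage: s.removed_ids for s in report.stages}
    assert removed["low_depth_samples"] == ["s6"]
    assert removed["low_read_taxa"] == ["A"]
    assert removed["low_prevalence_taxa"] == ["B"]
    assert removed["low_depth_samples_recheck"] == ["s5"]
    assert removed["unclassified_phylum_samples"] == ["s4"]
    assert list(out.sample_ids) == ["s1", "s2", "s3"]
    assert list(out.taxon_ids) == list("CDEFGH")
    report.validate()


def test_surviving_cells_never_altered(small_archive):
    tables, _, _ = small_archive
    archive = consolidate_tables(tables)
    out, _ = filter_archive(archive)
    assert out.counts.equals(archive.counts.loc[out.sample_ids, out.taxon_ids])


def test_idempotence_and_convergence(small_archive):
    # the cascade is an exact fixed point whenever its two final
    # sample-removing stages fire on nothing; otherwise those late sample
    # drops can pull boundary taxa below the read/prevalence thresholds,
    # and re-application converges in a few passes, never re-removing
    # samples at the depth stage
    tables, _, _ = small_archive
    archive = consolidate_tables(tables)
    once, first = filter_archive(archive)
    stages = {s.stage: s for s in first.stages}
    late_sample_drops = (
        stages["low_depth_samples_recheck"].n_removed
        + stages["unclassified_phylum_samples"].n_removed
    )
    twice, second = filter_archive(once)
    if late_sample_drops == 0:
        assert twice.counts.equals(once.counts)
        assert all(s.n_removed == 0 for s in second.stages)
    else:
        # output samples always satisfy the depth floor on the output taxa
        assert second.stages[0].n_removed == 0
        current = once
        for _ in range(5):
            nxt, rep = filter_archive(current)
            if all(s.n_removed == 0 for s in rep.stages):
                break
            current = nxt
        else:
            pytest.fail("cascade did not converge to a fixed point")


def test_closed_loop_with_planted_violations(small_archive):
    tables, _, truth = small_archive
    archive = consolidate_tables(tables)
    out, report = filter_archive(archive)
    stages = {s.stage: set(s.removed_ids) for s in report.stages}
    assert stages["low_depth_samples"] == set(truth.low_depth_samples)
    assert stages["low_read_taxa"] == set(truth.removed_taxa_low_reads)
    assert stages["low_prevalence_taxa"] == set(truth.removed_taxa_low_prevalence)
    assert stages["low_depth_samples_recheck"] == set(truth.removed_recheck_samples)
    assert stages["unclassified_phylum_samples"] == set(
        truth.removed_unclassified_samples
    )
    assert (out.n_samples, out.n_taxa) == truth.expected_filtered_shape
    # every planted violation was removed somewhere in the cascade
    planted_taxa = set(truth.rare_taxa) & set(archive.taxon_ids)
    assert planted_taxa <= report.removed_taxa()
    assert set(truth.high_unclassified_samples) <= report.removed_samples()


def test_stage2_basis_switch():
    # taxon X: 5 reads in the surviving sample, 10 in the low-depth one;
    # with sums on survivors (default) X falls under 8, on the full table
    # it survives with 15
    table = build_table(
        [[20, 5], [0, 10]],
        sample_ids=["keep", "drop"],
        taxon_ids=["Y", "X"],
        phyla=["Bacillota", "Bacillota"],
    )
    out_after, _ = filter_archive(
        table, min_sample_reads=12, min_taxon_reads=8, min_taxon_prevalence=1
    )
    assert "X" not in out_after.taxon_ids
    out_before, _ = filter_archive(
        table,
        min_sample_reads=12,
        min_taxon_reads=8,
        min_taxon_prevalence=1,
        taxon_sums_after_sample_filter=False,
    )
    assert "X" in out_before.taxon_ids


def test_removing_every_sample_is_reported_not_raised(caplog):
    table = build_table([[3, 4], [2, 2]])
    with caplog.at_level("WARNING"):
        out, report = filter_archive(table)  # all depths < 10,000
    assert out.n_samples == 0
    report.validate()
    assert report.stages[0].n_removed == 2


def test_report_reconciliation_is_enforced():
    table = build_table([[20000, 100], [15000, 200], [12000, 300]])
    _, report = filter_archive(table)
    report.validate()
    report.output_samples += 1
    with pytest.raises(ValidationError):
        report.validate()
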