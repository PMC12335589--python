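# Methods

This note documents the models, numerical choices and known limitations
behind `micropool`. Everything stated here is computed by the test suite
or by `scripts/acceptance.py`; nothing is asserted that the code does not
verify.

## Data model

The central container is a samples × taxa matrix of non-negative integer
read counts at genus level, with per-sample metadata (source project,
country, industrialisation setting, library layout) and per-taxon
metadata (genus and phylum labels, with the sentinel
`unclassified_phylum` marking reads unassigned at phylum level). Unknown
metadata values are always the literal string `unknown`, never empty
cells. Validation is strict and never repairs: duplicate or unmatched
identifiers, negative or fractional counts, and unrecognised category
values all raise. Count tables are TSV with samples as rows; a
`transpose` flag accepts the taxa-as-rows orientation some deposited
tables use.

## Project-level QC

Quality is judged from the read-tracking numbers the denoising stage
reports (reads in, reads entering chimera removal, non-chimeric reads
out), not from raw sequence data. Two rules apply, with boundary
semantics taken literally:

1. the project-wide fraction `sum(nonchimeric) / sum(input)` fails only
   when strictly below 0.5 (computed on totals, treating quality as a
   project property rather than a mean of per-sample fractions);
2. among the first `min(10, n)` rows in manifest order, the project
   fails when 5 or more rows have a chimeric fraction strictly above
   0.25.

The per-sample chimeric fraction uses reads entering chimera removal as
its denominator by default — chimeras are identified at that stage, so
`1 − nonchimeric/prechimera` is the fraction of that stage's input that
was chimeric — with raw input reads available as an alternative
(`chimera_denominator="input"`). A row with zero denominator gets
fraction 0 and a logged warning. The manifest order is whatever order
the tracking file supplies; permuting rows beyond the first ten cannot
change a verdict, and rescaling all read counts by a common factor
cannot either (both properties are tested).

Failing paired-end projects are re-analysed single-end; failing
single-end projects (and re-runs that fail again) are discarded. An
unknown layout offers no re-run and is treated as single-end, logged.

## Filter cascade

Five stages in fixed order, all inequalities strict (an entity exactly
at a threshold survives):

1. samples with total reads < 10,000;
2. taxa with < 80 reads summed over the stage-1 survivors;
3. taxa present (count > 0) in < 3 samples;
4. stage 1 re-applied to the remaining counts;
5. samples whose phylum-unclassified read fraction, on the post-stage-3
   counts, exceeds 0.10.

Stage-2 column sums are computed after the stage-1 sample drop by
default; whether the original archives computed them before or after is
not generally knowable from filtered outputs alone, so
`taxon_sums_after_sample_filter=False` exposes the alternative. Removing
every sample is reported, not raised.

**Idempotence is conditional, not absolute.** If stages 4 and 5 remove
no samples, the output is an exact fixed point of the cascade (the
stage-2/3 statistics are unchanged on re-application; this is tested).
But when those late stages do remove samples, a boundary taxon whose
reads were concentrated in them can fall below the read or prevalence
threshold on a second pass: the cascade, applied as published (taxon
filters before the final sample drops), is therefore not idempotent in
general. Re-application converges to a fixed point within a few passes
and never re-removes samples at the depth stage (output rows satisfy
the floor on the output taxa by construction of stage 4). The tests
assert exactly this conditional form.

## Diversity

Shannon uses the natural log by default (the base is a parameter);
`H = 0` for a single-taxon sample and `H = ln S` for a uniform profile
over `S` taxa (verified to 1e-9). All-zero samples are an error, never a
silent 0. Jaccard defaults to presence/absence; the abundance-based
variant `2B/(1+B)` (with `B` Bray-Curtis on counts — the form count
inputs produce in common R implementations) is provided because figure
provenance rarely records which was used. Pairwise matrices are computed
with `scipy.spatial.distance.pdist` and returned as labelled
`skbio.DistanceMatrix` objects (symmetric, hollow, validated); the
matrix path is cross-checked against the scalar definitions and against
scikit-bio's `beta_diversity` in the tests.

Country uniqueness is the distribution of all within-country pairwise
distances; countries with fewer than two samples have no pairs and are
skipped with a warning. Distances are meant to be computed on the
filtered table, so extremely rare taxa do not dominate presence sets.

The Mantel statistic is the Pearson correlation of the off-diagonal
upper triangles; the one-sided p-value uses the add-one estimator
`(1 + #{r* ≥ r}) / (1 + n_perm)` under joint row/column permutation of
the second matrix. An exhaustive mode enumerates all `n!` permutations
(n ≤ 8) and returns the exact permutation p-value; the stochastic
estimator is calibrated against uniformity under the null (KS check at
500 replicates) and the implementation is cross-checked against
scikit-bio's `mantel`. Permutation hits use a 1e-12 tolerance on the
correlation comparison so ties of equivalent relabelings are counted.

## Local Representation Index

Population shares are taken over every country in the population table
(countries without samples stay in the denominator and are flagged
`no_data`); sample shares are taken over archive samples with a known
country — `unknown` is excluded from the denominator. The two-branch
rule ρ vs −1/ρ leaves ρ = 1 ambiguous; it maps to +1 with status
`balanced` (detected at relative tolerance 1e-12). Raw values are
reported, never log-transformed. The index is scale-invariant,
antisymmetric under swapping the two share vectors, and never lies
strictly inside (−1, 1); all three properties are tested exactly. A
country with samples but no population entry is an error naming the
country.

## Accumulation analysis

Counts are binarised (presence = count > 0) after any rarefaction, so
the order is rarefy → binarise. Subsets of samples are drawn uniformly
without replacement; with-replacement sampling is deliberately not
offered. The SD reported is the sample SD across iterations (ddof 1),
which is exactly 0 at full depth. Curves are bit-for-bit reproducible
for a fixed seed. Internally the presence matrix is bit-packed
(`np.packbits`) so each draw's taxon union is a byte-wise OR plus a
popcount table, which keeps 1000-iteration curves on ~3000-sample
archives to seconds.

The exact expectation `E[U_k] = Σ_t [1 − C(n−m_t, k)/C(n, k)]` is
evaluated in log-space via `gammaln` (taxa with `n − m_t < k` are
certain to be drawn and contribute 1 exactly). It is non-decreasing and
concave on the integer depth grid, and the Monte-Carlo mean agrees with
it within 3 standard errors at every depth — with the SE floored by the
exact per-taxon absence variance, because the empirical SD degenerates
to zero when every draw happens to cover all taxa.

**Pooled curves do not dominate group curves at every depth.** A small
country whose taxa are locally dense can exceed the continental
expectation at small k, because its occupancy fractions are diluted in
the pool; this was verified numerically, so the tested dominance
property is the one that is a theorem: the continental full-depth value
(the taxon union) dominates every country's, and every expectation is
monotone in depth.

Default depth grid {5, 10, 25, 50, 100, 250, 500, 1000, 2000, 3000},
clipped to each group's size, with the group's full size appended so
parameter-recovery at full depth is always available. Rarefaction
presets of 9000 and 1000 reads per sample are provided; samples below
the depth are dropped from that regime only, and the number dropped is
recorded on each curve.

## Synthetic archive generator

The generator emulates the statistical shape of a continental amplicon
archive: 33 projects over 9 of 13 South American countries, project
sizes lognormal (median 60, clipped to [9, 881], giving ~3000 samples
and a mean near 110 per study), per-sample depths lognormal with median
3.37 × 10⁴ reads, a taxon pool of 2246 genus-level identifiers, and a
setting mix of industrialised / non-industrialised / unknown projects
with a disease-context flag on non-industrialised ones.

Per sample: the country pool is a continental core (35% of the abundant
taxa, retained per sample with probability 0.9 × core retention 0.35)
plus country-private taxa (25 per country) plus shared regional taxa
assigned to random country subsets; each pool taxon enters the sample's
support by an independent Bernoulli draw whose probability (0.10–0.40,
drawn per country) is the country's heterogeneity knob — lower
retention means fewer shared taxa between compatriots and measurably
higher within-country Jaccard medians (rank agreement tested over
seeds). Reads are allocated multinomially over the support with
lognormal taxon propensities (σ = 3, chosen so per-sample observed
richness of ~100–150 genera and Shannon near 2–3 emerge at the default
depth). Absence arises from pool membership and sampling; there is no
explicit zero-inflation parameter.

Planted filter violations are constructed with margins so they fall on
the correct side of the default thresholds: low-depth samples draw
depths in [1000, 9500] while everything else is floored at 12,000
reads; rare taxa (50% of the pool; ~89% failing on total reads < 80 and
the rest on prevalence ≤ 2, mirroring the removal split real archives
show) are added on top of the multinomial allocation and never placed
in low-depth samples; high-unclassified samples have their
phylum-unclassified propensity share pinned in [0.15, 0.35] versus 0.03
elsewhere. The remaining filter outcome is *re-derived* at generation
time directly from the thresholds (row/column sums, not the cascade
code): abundant taxa whose lognormal draw is tiny can genuinely fall
under the thresholds, and removing a stray high-count low-prevalence
taxon can drag a sample below the depth floor at stage 4 — both are
real cascade behaviour and are recorded in the ground truth, so the
closed-loop tests compare two independent routes to the same sets.

Tracking tables are generated independently of the count tables (the QC
logic consumes only stage totals); a configurable fraction of projects
is planted with chimeric fractions in [0.45, 0.70] so both QC rules
fail for them.

What the generator does **not** emulate: compositional covariance
between taxa, batch/primer effects between projects, phylogenetic
structure, sequence-level error, and per-run error-model variation.
Passing tests therefore demonstrate the correctness of the pipeline's
bookkeeping and estimators under a realistic marginal structure, not
robustness to every artefact of real amplicon data.

## Problem sizes

Unit tests run on a ~100-sample, 200-taxon archive; whole-pipeline
checks use the default scale (~3000 samples × 2246 taxa) with reduced
iteration counts where the estimate is exact anyway (the full-depth
accumulation value is deterministic, so 20–100 iterations suffice
there, while estimator-calibration checks use the published 1000
iterations on small matrices where the exact oracle is cheap).
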