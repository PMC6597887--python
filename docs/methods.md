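# Methods

## Data model

The core entity is the phenotypic observation: a trait expression recorded
in an experimental unit, stored in an entity–attribute–value style table
that references its explanatory metadata rather than encoding traits as
columns. One raw-observation table serves all data types through separate
typed value fields — `value_absolute`, `value_percent`, `value_count`,
`value_score_numeric`, `value_score_text` — because more than one type can
legitimately apply to a single observation (e.g. diseased plants as a count
*and* a percentage) and typed columns keep calculation, sorting and
validation straightforward for external statistical software. Validation is
methodology-driven: the method type implies which field must be populated
(measurement → absolute value with a unit, count → integer, percentage →
[0, 100], numeric/text score → a value from the attached scoring key);
extra populated fields are permitted.

An observable variable is a **methodology**: a trait descriptor (grouped
into the closed set abiotic_stress / biotic_stress / agronomy / morphology /
phenology / physiology / quality) paired with a concrete method, optionally
carrying the phenological stage recommended for observation. One application
of a methodology over an experiment's plots at a date is a **measurement**;
raw observations hang off measurements and plots. Experiments are one-site /
one-season; multi-site series are sets of experiments under a project code.

Natural compound keys are primary keys everywhere the domain provides them
(accession = holding institute + accession number per the multicrop passport
convention; experiment = project + institute + code + initiation date;
plot = experiment + lane + plot). Only pictures and uploads, which have no
natural identity, use surrogate ids. Foreign keys are enforced by the
embedded SQLite backend; deletes cascade only into the picture link tables,
never into observations. Aggregated observations are materialized by
`stats.aggregate` rather than recomputed per query, since field data arrive
in bursts and are read far more often than written.

Phenology codes are free strings (BBCH recommended, not enforced) validated
only for non-emptiness; `homogeneity_code` is stored verbatim with no
semantics; data availability is a three-level enum (public / project /
owner) without authentication; the method `parent` and `denominator`
relations are stored references with acyclicity enforced on insert, no
further semantics. The spreadsheet-mapping attribute registry is the closed
set {accession_number, accession_name, holding_institute_code, lane, plot,
block, observation_date, stage, homogeneity_code}, versioned in
`core.ATTRIBUTE_REGISTRY_VERSION`.

## Randomization

A plan is a pure function of (request, seed). Randomization is a
Fisher–Yates shuffle per block, each block drawing from its own PRNG stream
spawned from the single request seed (`numpy` SeedSequence), so adding a
block never perturbs the randomization of earlier blocks. In the augmented
design, entries are assigned to blocks by a seeded shuffle followed by
round-robin, which guarantees block sizes within one; every block contains
every check exactly once. Blocks occupy contiguous ranges of the fill
sequence. Checks may not also appear among entries — overlapping lists are
rejected rather than silently deduplicated.

Orientation plots (sowing aids, no accession) are inserted after every k-th
data plot, inherit the preceding plot's block, and are excluded from sowing
lists and all statistics. Layout maps the fill sequence lane by lane:
row-major numbers plots 1..k in every lane; serpentine reverses the
numbering in even lanes (k..1), including a partial final even lane, which
is numbered from k downward so the direction rule stays uniform.

## Check-based adjustment (augmented designs)

Only the checks are replicated, so they carry the block information. With
check values `x_cj` (check c, block j):

    b_j      = mean_c(x_cj) − mean_cj(x_cj)      (estimated block effect)
    adjusted = raw − b_j                          (entries)

and a check's adjusted value is its mean across blocks. Blocks missing any
check value get no effect estimate; their entries are flagged unadjustable
(NaN) rather than silently passed through. The adjustment removes all
between-block differences: adding constants c_j per block moves every
adjusted value by mean(c_j) and nothing else, so adjusted *differences* are
block-shift-invariant and values are exactly invariant for mean-zero shifts.

## Descriptive statistics

Per accession over its field-replication plots: mean, median, sample
standard deviation (n−1), standard error sd/√n, min, max, n, and the
biased Fisher–Pearson moments on m_k = (1/n) Σ (x − x̄)^k:

    g1 = m3 / m2^(3/2)        (skewness; null if n < 3 or m2 = 0)
    g2 = m4 / m2² − 3         (excess kurtosis; null if n < 4 or m2 = 0)

sd/se are null at n = 1. Text scores cannot be averaged and aggregate to the
modal code only (ties broken by scoring-key order). Raw data are always
retained; aggregates are presentation layers.

Harmonization maps values linearly to the universal 1–9 grade:
`grade = round(1 + 8·(x − min)/(max − min))`, reversed (10 − grade) when
lower values are better; identical values all map to grade 5 by convention.
Grades are endpoint-exact and monotone by construction — and deliberately
*not* a substitute for the raw values, whose reference range floats over
time. Multi-trait ranking averages ranks on ties (rank 1 = best under each
trait's direction), combines them by user weights summing to 1, and assigns
accessions missing a trait the worst rank plus a flag so deficiencies stay
visible.

## Import gates

Imports are all-or-nothing at file level. Three gates run before anything is
written: (1) duplicate detection — the SHA-256 of the file bytes must not
match an *active* upload of the same experiment; (2) plot–genotype
consistency — each row resolves to a plan plot by (lane, plot), or by
accession when it occupies a unique plot, and the stated accession must
match the plan (an accession claimed for an orientation plot, or an unknown
plot address, is a mismatch); (3) observation validation — every non-empty
cell must satisfy its methodology. Empty cells and "NA" are skipped and
counted, not errors. Replacement deletes the old upload's observations,
marks it replaced and imports the new file in one SQLite transaction, so a
failing replacement leaves the store bit-identical. All-or-nothing semantics
were chosen over partial acceptance because they keep replacement and
provenance (every observation → exactly one active upload → its mapping
protocol) trivially consistent.

## Synthetic data

The fixtures module emulates a single-methodology oat evaluation trial under
the additive phenotype model

    value(plot) = μ + g[accession] + b[block] + ε,   ε ~ N(0, σ_e²)

with defaults μ = 100, σ_g = 10 (genotype spread), σ_b = 2, σ_e = 1 — i.e.
block heterogeneity twice the plot error, the regime in which augmented
designs are worth their check plots, on a measurement scale resembling plant
height in cm. Block effects are drawn and then centered to sum to zero, the
standard identifiability constraint; without it the check adjustment
recovers genotype values only up to the mean block effect, which is not
estimable. Draws come from named seed-derived streams, so a truth record
reproduces its trial byte-for-byte.

What the generator does *not* emulate — genotype×environment interaction,
spatial trend within blocks, non-Gaussian and censored traits, missing
plots, multi-site correlation — bounds what the passing tests show: they
validate bookkeeping, randomization combinatorics and the adjustment algebra
under the model's own assumptions, not the adjustment's robustness on messy
field data.

## Verification sizes and numerical choices

The acceptance checks use problem sizes chosen to exercise the combinatorics
while remaining quick: 100 augmented requests (1–5 checks, 1–8 blocks,
5–200 entries, 4–24 plots/lane) and 50 block requests for the design
invariants; a 3-check / 4-block / 20-entry trial (32 data plots, 3
methodologies, 96 observations) for the import round trip; 1000 random
samples (n = 2..50) against an independent stdlib/scipy moment oracle at
1e−9; and, for the raw-vs-adjusted RMSE comparison, 200 replicates of a
representative screening trial (60 entries, 6 blocks, 3 checks) — with only
~20 entries the per-replicate RMSE is itself so noisy that the comparison is
uninformative even though the adjustment's error variance (≈1.3 σ_e²) is
far below the raw variance (≈4.3 σ_e²).

Ties in the stage sort of field-book columns break by trait name; stage
strings sort by their first numeric token (nulls last, i.e. unscheduled
traits observed opportunistically). CSV null convention: empty string and
"NA" read as null, written as empty. Seed amounts in sowing lists use
`ceil(seeds_per_plot / germination_rate)`; rates of zero (or missing) are
flagged, never divided by.

## Limitations

Latin-square and lattice randomization are accepted as experiment metadata
but not generated; mixed-model (REML) analysis, genotype×environment
modelling and the normalized rank product are out of scope — the adjustment
here is the classical single-factor check correction, adequate for ranking
within one trial but not a substitute for a proper multi-environment
analysis. The store is single-user, single-file SQLite; treatment
consistency on import is not checked (only genotypes are). Image support is
cataloguing and linking only, no analysis.
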