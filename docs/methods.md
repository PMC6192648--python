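# Methods

This note documents the models, thresholds and design choices behind
`funkfams`, and what the synthetic fixtures do and do not demonstrate.

## Family screening

A catalog family enters downstream analysis iff it has at least
`min_unique = 3` distinct member sequences and a truncated-member fraction
of at most `max_truncated_frac = 0.5`. Both boundaries are pinned by tests:
2 unique sequences fail and 3 pass; exactly half truncated passes and any
more fails (the inequality is strict). "Truncated" means the member lacks a
start **or** a stop codon (inclusive or, the plain reading of the flags).
Uniqueness is computed on normalized sequences: uppercase, exactly one
trailing `*` stripped. An internal `*` is rejected as a likely
pseudogene/frameshift artifact rather than silently repaired — all readers
in this package reject malformed input instead of skipping it, because a
silently dropped line corrupts every downstream count.

Annotation status is exact: a member matches a database entry iff the
normalized sequences are byte-identical, and the family is annotated iff
any match carries at least one domain accession. Exact full-length
100%-identity matching is equivalent to string equality, so the
implementation is a hash index keyed by sequence; an all-pairs
string-comparison oracle verifies this on dozens of random fixtures. A
matched database entry with an *empty* domain list (a protein deposited
without domain assignments, e.g. "hypothetical protein") is recorded in
the hit list for transparency but does not flag the family as annotated —
the definition is domain-centric. A non-exact homology search mode is
declared in the configuration (`annotation_mode`) but deliberately
unimplemented; it only makes sense for catalogs whose genomes are not
already represented in the annotation databases.

## Breadth and selection

Breadth at a rank is the cardinality of the set of non-null taxon *names*
among members at that rank. Names, not taxon-id paths, because the lineage
table is name-based: two genomes sharing a class name count once. Members
with missing lineages (or null cells) contribute nothing; a family of
lineage-less members has breadth 0 everywhere and can never be selected —
the conservative choice, since unknown lineages should not inflate breadth.
With complete lineages the counts are non-increasing from species to
domain, a property asserted on every generated fixture.

FUnkFams are the filtered, unannotated families with ≥ `min_distinct = 2`
distinct classes. No canonical ranking function exists for "phylogenetic
breadth", so this package uses lexicographic ordering on
(distinct domains, distinct phyla, distinct classes, n_unique), descending,
with family id as a final deterministic tiebreak; output headers label the
score as this package's convention.

## Metagenomic profiling

Per read, the best hit maximizes bit score, with ties broken by lower
e-value then lexicographically smallest subject id (fully deterministic).
A read is accepted iff `pct_identity >= 99.0` and `align_len >=
read_length`. The 12-column tabular alignment format carries no query
length or coverage, so "over the whole length of the read" is
operationalized against the per-sample read length from the metadata table
— appropriate for fixed-length short-read data. Identity is taken from the
`pident` column as reported by the aligner and is not recomputed.

RPKG divides the accepted-read count by family length in kb — mean member
protein length in amino acids × 3, since reads are DNA and the statistic
is per kilobase of gene — and by the sample's genome equivalents (library
depth / average genome size, estimated upstream and supplied as metadata).

The entropy pre-filter keeps families whose binary presence entropy
H(p) = −p·log₂p − (1−p)·log₂(1−p) reaches the top `top_fraction = 0.25`
of the empirical distribution; the threshold is the linear-interpolation
quantile and ties at the threshold are retained (so equal entropies are
never split arbitrarily, and `top_fraction = 1` retains everything). The
phylum pre-filter keeps families with ≥ 2 distinct phyla.

Bray–Curtis dissimilarities are computed on RPKG profiles (scipy's
implementation, cross-checked against the closed form in tests). A sample
in which no selected family was detected has an undefined dissimilarity to
everything and is excluded from the matrix; excluded samples are listed in
the run manifest. The within/between-environment comparison uses a
one-sided Mann–Whitney U (between > pooled within); the test is the
package's choice of a standard nonparametric two-sample procedure.

## Association model

Within each stratum, for each eligible covariate and family:

    presence ~ intercept + adjustment terms + covariate term(s)

fit by maximum likelihood (Newton/IRLS, coefficient tolerance 1e-8, max
100 iterations, via statsmodels). Categorical covariates use treatment
coding against the most frequent level (alphabetical tiebreak); numeric
covariates are standardized within the stratum, so their coefficients are
per-SD log-odds — stated in the output header. Wald t-tests use
df = n − p, matching the small-sample t rather than a normal z.

Eligibility requires at least two covariate levels with more than four
observations each (≥ 5 after dropping missing values). For continuous
covariates, where per-value counts are meaningless, the same observation
budget is applied to the whole column: ≥ 2 distinct values and ≥ 10 total
observations.

Perfect/quasi-separation is detected when any fitted probability is within
1e-10 of 0 or 1 with a coefficient magnitude above 15, or when standard
errors are non-finite; such fits are flagged `SEPARATED` and excluded from
the FDR pool rather than penalized, keeping the estimator faithful to the
plain logistic model. Families with constant presence in a stratum, and
covariate/stratum combinations with too few samples, are `SKIPPED_INELIGIBLE`.

Benjamini–Hochberg correction pools p-values across families within each
(stratum, covariate) pair — the narrowest pool consistent with fitting
models per stratum; a `global` pool is available as a configuration option.
Samples are treated as independent (repeated visits from one subject are
not collapsed); this caveat matters for longitudinal designs.

Calibration and power are verified by simulation: under the null
(presence independent of covariates; 20 replicates of 200 families × 100
samples) the raw p < 0.05 rate sits inside the 99% binomial band around 5%
and q < 0.05 discoveries are (almost always exactly) zero; a planted
+2 log-odds effect at 100 samples per stratum is recovered with the correct
sign at q < 0.05 in ≥ 90% of replicates.

## Synthetic fixtures

The generator emulates the structure of a family catalog plus two
metagenome collections at desk scale. Defaults, chosen once as realistic
study conditions: 12 families of 3–6 members around 250 amino acids long
(typical family size and length for homology-clustered reference-genome
catalogs), of which 4 are planted FUnkFams (broad: ≥ 2 classes from ≥ 2
phyla), 3 annotated, 2 unannotated-but-narrow and 3 failing quality
control; a toy taxonomy of 2 domains × 3 phyla × 2 classes; two
environments ("ENV_A"/"ENV_B") of 10 samples each with 100-bp reads,
genome equivalents uniform on (5, 30), one categorical and one numeric
covariate; 1–20 accepted reads per present family; decoy alignments (low
identity, short, unknown subject, duplicate secondary hits) at ~0.3 per
accepted read; and a planted +3 log-odds effect of the categorical
covariate on the first FUnkFam in ENV_A.

Member sequences are point-mutated copies of a random ancestor. This is
*not* evolutionarily realistic — no selection, no indels, no codon
structure — and the reads are bookkeeping entries, not simulated sequences
with errors. That suffices here because no pipeline operation measures
sequence similarity except exact equality and the alignment thresholds act
on the tabular columns. Consequently, passing tests demonstrate the
*logic* of the pipeline (filters, counting, normalization, statistics) on
inputs whose truth is known by construction; they say nothing about
aligner behavior, database completeness or annotation quality on real
data. Real-scale results additionally depend on the catalog and database
versions used.

Determinism: one integer seed fixes every emitted byte, and pipeline
reruns on identical inputs are byte-identical outside the manifest (which
holds the run timestamp). Problem sizes in the test and acceptance suites
(12–200 families, 10–100 samples, 20 replicates) are the package's own
desk-scale study conditions.
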