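# funkfams

Most microbial genes have no known function, and the fraction is growing as
sequencing outpaces experimental characterization. `funkfams` implements a
pipeline for building a "most wanted" list of such genes: it screens a
catalog of protein families for robustly defined, full-length families with
**no annotated protein domains**, ranks them by **phylogenetic breadth**,
quantifies their **presence and abundance in shotgun metagenomes**, and
tests their presence for **association with sample covariates**. The
resulting Function Unknown Families (FUnkFams) are conserved across diverse
organisms and detectable in real environments — exactly the genes worth
prioritizing for functional characterization.

It is aimed at microbiome and comparative-genomics researchers who have a
pre-clustered protein-family catalog (e.g. from iterative homology
clustering of reference proteomes), one or more domain-annotation databases,
and per-sample short-read alignments in BLAST tabular format.

## Method

1. **Quality filtering.** A family is kept only if it has ≥ 3 unique member
   sequences and at most 50% of members truncated (missing a start or stop
   codon) — truncation fraction strictly greater than 0.5 fails.
2. **Annotation screening.** A family counts as annotated iff any member is
   a **100%-identity, full-length** match to an annotation-database sequence
   carrying ≥ 1 domain accession. Because exact full-length identity is the
   criterion, the search is realized as a hash lookup on the normalized
   amino-acid sequence — bit-exact, no aligner needed.
3. **Breadth and selection.** Each family's members are mapped to named
   taxa at eight ranks (species … domain); breadth at a rank is the number
   of distinct names. FUnkFams are the filtered, unannotated families
   spanning ≥ 2 classes, ranked by (distinct domains, phyla, classes,
   unique sequences) descending.
4. **Metagenomic profiling.** Each read keeps its best hit (highest bit
   score); it counts for a family iff identity ≥ 99% over the whole read.
   Presence = ≥ 1 accepted read. Abundance is RPKG:
   `count / (mean member length in aa × 3 / 1000 kb) / genome equivalents`.
   Ecology pre-filters keep families with presence entropy in the top 25th
   percentile and members from ≥ 2 phyla; Bray–Curtis dissimilarity
   (`1 − 2Σmin(xᵢ,yᵢ)/(Σxᵢ+Σyᵢ)`) compares samples within and between
   environments (one-sided Mann–Whitney U).
5. **Association testing.** Per stratum and eligible covariate, each
   family's presence is fit with logistic regression
   (`presence ~ intercept + adjustment + covariate`), covariate terms get
   Wald t-tests (df = n − p), and p-values are Benjamini–Hochberg corrected
   across families within each (stratum, covariate) pair.

A seeded synthetic-data generator (`funkfams simulate`) emits a complete,
internally consistent fixture — catalog, lineages, annotation database,
per-sample alignments, metadata — plus a ground-truth manifest, so the whole
pipeline is testable without any external databases.

## Worked example

```sh
funkfams simulate -o fixture --seed 1
# wrote fixture to fixture: 12 families (4 planted FUnkFams), 20 samples

cat > config.yaml <<'EOF'
catalog_fasta: fixture/catalog.faa
membership_tsv: fixture/membership.tsv
lineage_tsv: fixture/lineage.tsv
annotation_dbs:
  - {name: DB1, fasta: fixture/annotation_db.faa, tsv: fixture/annotation_db.tsv}
m8_dir: fixture
sample_metadata: fixture/metadata.tsv
out_dir: out
covariates: [pheno_cat, pheno_num]
EOF

funkfams -v all -c config.yaml
# screen: 12 families in, 9 pass filters, 6 unannotated, 4 FUnkFams
# profile: 20 samples, 4/4 FUnkFams detected, 2 pass ecology pre-filters
# associate: 2 OK tests, 0 discoveries at q < 0.05
```

Of 12 simulated families, 9 survive the uniqueness/truncation filters, 6 of
those have no exact-match domain annotation, and 4 also span ≥ 2 classes —
exactly the planted FUnkFam set. `out/funkfams.tsv` lists them by breadth
rank:

```
family_id  n_domains  n_phyla  n_classes  n_unique  distinct_at_rank
FAM0009    2          3        3          5         3
FAM0007    2          3        3          4         3
FAM0012    2          2        2          5         2
FAM0006    2          2        2          4         2
```

All four are detected in the simulated metagenomes; the two with the most
variable presence patterns (entropy in the top quartile) and ≥ 2 phyla enter
association testing. The remaining outputs — count/presence/RPKG matrices,
prevalence, entropy, Bray–Curtis matrix, beta-diversity summary, association
results — are TSVs under `out/`, with run provenance in `out/manifest.json`.

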