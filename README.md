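# varannot

Desk-scale variant functional annotation: a keyed multi-table annotation
store with variant/gene/region/batch query logic, annotation principal
components (aPCs) with rank-based PHRED scaling, and an annotated genomic
container format that holds a cohort's genotypes and their aligned
functional annotations in one block-compressed, random-access file.

## Who this is for

Whole-genome and whole-exome sequencing studies annotate every observed
variant with scores describing protein impact, conservation, epigenetics,
allele frequencies, clinical assertions and more, then carry those
annotations into downstream rare-variant association analysis.  `varannot`
re-implements that stack at a scale that runs on a laptop: the database is
synthesized rather than downloaded (20 TB of genome-wide annotations is out
of scope by design), but every mechanism — the primary-key join, the score
aggregation, the container format, the query surface — is the real thing
and fully tested.

## The model in brief

**Primary key.** Every variant is identified by the string
`chrom-pos-ref-alt` (e.g. `19-44908822-C-T`), 1-based, alleles kept in
their VCF-anchored form (`1-10253-CTA-C` is a 2-bp deletion).  All tables
join on this key; SNVs and indels live in separate store partitions.

**Rank-based PHRED scaling.** A raw score with descending rank *r* among
*N* maps to

    PHRED = −10 · log10(r / N)

so PHRED > 10 means the top 10% of the ranking population, PHRED > 20 the
top 1%.  Ties take the largest rank in their group, which keeps the top-10%
reading conservative.

**Annotation principal components.** For a functional category with
component scores X (e.g. the eight conservation scores), each column is
median-imputed and standardized (mean 0, sample SD 1), the first principal
component of the sample covariance is extracted with the sign fixed so the
loadings sum ≥ 0, and the per-variant projection is PHRED-scaled over all
SNVs in the store.  The result is one interpretable score per category
(`apc_conservation`, `apc_epigenetics`, ...), higher = more evidence of
function.

**Annotated container (`.agds`).** Genotypes are stored as a 2-bit array
with (ploidy, sample, variant) dimensions — allele indices 0–2 direct,
escape code 3 for missing/overflow with an explicit overflow list and a
per-variant index vector — alongside one annotation channel per field.
Every channel is cut into blocks of `block_size` variants and each block is
LZMA- or zlib-compressed independently, so reading a selection decompresses
only the blocks it overlaps.  On rare-variant cohorts the container is
three orders of magnitude smaller than the VCF text.

## Worked example

```
$ varannot fixtures make --out demo --seed 17 --contigs 1x2000 --samples 50
fixtures written to demo

$ varannot annotate --vcf demo/cohort.vcf --db demo --out demo/cohort.agds
6020 variants -> demo/cohort.agds (matched 6020, unmatched 0)

$ varannot query region --chrom 1 --start 1 --end 500 --db demo --keyword pathogenic
1503 variants; 950 with PHRED>10
75 match keyword 'pathogenic'

$ varannot query variant 1-2-T-A --db demo
== 1-2-T-A ==
  FLAG cadd_phred > 10 on the PHRED scale (top 10%): cadd_phred=10.4148

$ varannot query gene GENE2 --db demo --out gene2.csv
520 variants in GENE2
results written to gene2.csv
```

What the numbers mean: the fixture contig has 2000 bases, so the catalog
holds 3 × 2000 = 6000 possible SNVs plus 20 sampled indels; all 6020 are
present in the store, hence `matched 6020`.  The region query summarises the
1503 variants keyed in positions 1–500 (1500 SNVs plus 3 indels); 950 carry
at least one PHRED-scaled score above 10, and 75 rows of the display table
contain the substring "pathogenic" (ClinVar assertions are sparse in the
fixture).  The single-variant query prints only the evidence that fired —
here one integrative score in the genome-wide top 10%.  The gene export is
a CSV with 33 columns: the variant key plus the 32 standard region-table
annotations.

The same operations are available as library calls (`varannot.build_store`,
`varannot.compute_apcs`, `varannot.annotator_pipeline.annotate_vcf`,
`varannot.query_engine.query_region`, ...).

## Scope notes

The physical `.agds` byte layout is this package's own (documented in
`docs/methods.md`); it reproduces the logical layout of annotated-GDS
containers — 2-bit genotypes, index vector, aligned variable-length
annotation channels, independent block compression — but is not
binary-compatible with CoreArray GDS readers.  Web front-ends, cloud
workflow wrappers and genome-wide precomputation are out of scope.
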