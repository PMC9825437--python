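# Methods

This note records the models, conventions and numerical choices behind
`varannot`, in the spirit of a statistical software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Variant identity

A variant is `(chrom, pos, ref, alt)`: chromosome label without a `chr`
prefix (1–22, X, Y, M; MT normalised to M), 1-based position of the first
reference base, uppercase ACGT alleles, `ref ≠ alt`.  The canonical string
form `chrom-pos-ref-alt` is the join key of every table and channel, and
parsing is the exact inverse of formatting.

Indels are deliberately **not** left-normalised or trimmed beyond their VCF
representation.  Exact string equality is the join mechanism between
genotype data and annotation tables, so the key must match the source
tables verbatim; re-trimming would silently break the join.  Consequence:
two representations of the same indel are distinct keys here, and allele
normalisation against a reference FASTA is a documented non-goal.

Point queries (`chrom-pos`) return only variants **anchored** at that
position; a deletion spanning the queried base but anchored upstream is not
returned.  This is the simplest contract consistent with exact-match
semantics, and it is what the batch and list expansions use.

Classification: SNV (both alleles length 1), insertion (|alt| > |ref|),
deletion (|ref| > |alt|), MNV (equal lengths > 1).  The store keeps two
partitions, SNV and indel; MNVs are routed to the indel partition so the
partition pair stays exhaustive.

## Schema registry

The shipped default schema has 160 fields across 12 functional categories
(Variant Category, Allele Frequencies, ClinVar, Integrative Scores, Protein
Functions, Conservation, Epigenetics, Chromatin States, Local Nucleotide
Diversity, Mutation Density, Mappability, Proximity), a 20-field essential
subset, a 17-block single-variant display layout, and a 32-column region
table.  Field names follow the sources such a database integrates (CADD,
GENCODE, ClinVar, gnomAD/TOPMed/1000G frequencies, GERP/PhyloP/PhastCons,
ENCODE marks, Umap/Bismap); where a category needs more members than the
individually famous scores provide, plausibly named per-category tracks
fill it out.  Counts are validated at load when the config declares
`expected_counts`; duplicate names, unknown categories/blocks, and
essential or region columns absent from the full set are hard errors.

The display layout names sixteen conventional blocks (Basic, ClinVar,
Variant Category, three allele-frequency blocks, Integrative Score, Protein
Function, Conservation, Epigenetics, Transcription Factors, Chromatin
States, Local Nucleotide Diversity, Mutation Density, Mappability,
Proximity) plus a seventeenth Histogram/Distribution context block; the
blocks partition the displayed fields exactly.

Missing sentinels: NaN for numeric fields, the empty string for
categorical/text/flag fields.  Sentinels are uncounted in every summary.

## Annotation store

Per-category delimited tables (key column `variant_vcf`) are outer-joined
on the key.  Every key seen anywhere yields exactly one record; a field
never assigned keeps its sentinel; two *different* non-missing values for
the same (key, field) abort the build listing the collisions — surfacing
upstream data errors was judged more valuable than last-write-wins.

Backend: in-memory pandas partitions indexed by key string, a dict rsID
alias index (separate alias table, many-to-many), and per-chromosome sorted
position arrays queried by binary search.  The backend contract is
observable behaviour only — every range/point/gene query must equal a
brute-force linear scan, which the tests enforce on fixtures of up to a few
thousand records.  Gene queries resolve a symbol through a GTF/GFF3 gene
model (gffutils, in-memory) to the footprint spanning min start to max end
over all the gene's transcripts, with no flanking.

## aPCs and PHRED scaling

Standardization: per column, missing entries are imputed to the column
median first, then the column is z-scored with the sample (n−1)
denominator; constant columns map to zeros.  Median imputation is robust to
the heavy tails synthetic and real annotation scores share, and keeps the
procedure deterministic.

First principal component: eigendecomposition of the sample covariance of
the standardized matrix; the loading sign is fixed by `sum(loadings) ≥ 0`
(first nonzero loading positive on a zero sum) so that higher aPC always
reads as more evidence.  The tests cross-check against an independent SVD
route at 1e-8.

PHRED transform: `−10·log10(r/N)` with descending rank `r` (rank 1 = most
functional), ties assigned the largest rank of their group.  The formula is
fixed by the anchor PHRED 10 ⇔ top 10%; the tie rule guarantees the
fraction above any threshold never exceeds the nominal rank fraction.
The ranking population is all SNV records in the store — at desk scale the
store *is* the genome — and indels receive no aPCs.  A grouping whose
components are all missing leaves its aPC at the sentinel with a warning;
a grouping with fewer than two components is a configuration error.

## Summaries, flags, display

Default evidence rules: PolyPhen score = 1 (probably damaging), SIFT score
= 0 (deleterious), ClinVar significance containing the token "pathogenic"
(case-insensitive — so "Pathogenic/Likely_pathogenic" and also
"Likely_pathogenic" alone fire; token matching is documented rather than
curated), and any PHRED-scaled field above 10.  Rules only fire on
non-missing values.

Region summaries tally: an allele-frequency histogram over fixed log-spaced
bins [0,1e-4), [1e-4,1e-3), [1e-3,1e-2), [1e-2,1e-1), [1e-1,0.5), [0.5,1]
(the edges are recorded in the output; the AF per record is the first
non-missing of `af_topmed`, `af_gnomad`, `af_1000g`, also recorded);
GENCODE category counts; ClinVar significance counts; functional-consequence
counts; and the number of variants with any PHRED-scaled field > 10.
Summaries are additive over disjoint record sets.

Keyword filtering matches a case-insensitive substring against the rendered
32-column row of each record (numbers rendered to 6 significant digits);
empty text keeps everything; filtering is idempotent.

## Container format

Logical layout: sample IDs; parallel variant arrays chrom/pos/ref/alt; an
optional genotype channel; one channel per annotation field.  Genotypes are
2-bit slots ordered variant-major, then sample, then ploidy fastest, first
slot in a byte at the least-significant bit pair.  Codes 0–2 are literal
allele indices; code 3 is an escape meaning "missing, unless an overflow
entry `(variant, sample, slot, value)` says otherwise".  The per-variant
index vector is 1 where the variant owns overflow entries — realising the
"index vector indicates the bit width" contract without variable-width
packing, which is simpler, testable and semantically equivalent at
ploidy 2.  Phasing is not recorded; allele order within a genotype is
preserved as given.

Physical layout (this package's own; deliberately *not* CoreArray GDS
compatible):

```
magic  b"AGDS\x01\n"
u64le  compressed header length H
bytes  zlib-compressed JSON header (version, codec, block size, counts,
       channel directory with per-block [offset, compressed, raw] entries,
       overflow list)
bytes  data blocks
```

Every channel is cut into blocks of `block_size` variants (default 1024),
each block compressed independently with the container codec — LZMA
(default; best ratio), zlib, or none.  Text channels encode a block as
little-endian uint32 lengths followed by the UTF-8 payload.  Random access
touches only the blocks a selection overlaps; the reader counts
decompressions so tests can verify the contract.  Appending a channel
copies existing compressed blocks byte-verbatim and rewrites the directory.
Validation decodes every block, checks channel lengths, index-vector
consistency and within-chromosome position sortedness, and reports per-check
pass/fail instead of raising on corrupt data.

Sample IDs are stored as a compressed channel rather than in the plain-text
header so the header stays small on large cohorts.

## Annotator pipeline

The annotator streams a VCF (pysam; plain or bgzip), splits multi-allelic
sites into per-ALT keys (symbolic and `*` alleles skipped with a warning
and counted), looks each key up in the store, and writes the container in
input order.  Genotypes are recorded per ALT: carriers of a sibling ALT at
a multi-allelic site count as reference for this ALT's channel.  Unmatched
variants are kept with all-sentinel annotations — the container must mirror
the cohort — unless `--drop-unmatched` is given.  The run manifest records
input checksum, counts (matched + unmatched + skipped = read), chunk size
and per-chromosome timing; the pipeline contains no randomness, so equal
inputs give byte-identical containers, chunk size is invisible, and
per-chromosome runs merged in chromosome order are byte-identical to a
single pass (the merge copies logical content and re-blocks).

Variant lists (CSV/TSV first column, or VCF) produce sites-only containers;
point and rsID rows expand to all matching alleles, emitted adjacently in
input order, and per-row parse failures are collected while the run
continues.  Batch queries cap the input row count (default 10,000,
configurable) and reject oversized files before any annotation work.

## Synthetic data

The fixture generators emulate the shape of the real inputs, not their
biology:

* **Catalog** — every possible SNV on seeded random contigs (3 per base)
  plus sampled 1–5 bp indels, coordinate-sorted.
* **Annotation tables** — numeric components of each aPC grouping are one
  shared per-variant latent factor (SD 1) plus independent Gaussian noise
  (SD 0.3), chosen so the first PC demonstrably recovers the latent factor
  (the tests require correlation > 0.95); allele frequencies follow
  10^Uniform(−5, −0.5); ClinVar labels are sparse (10%); ~5% of variants
  get rsID aliases, a few deliberately multi-allelic; PHRED-scaled source
  fields are drawn from the −10·log10(Uniform) marginal.
* **Cohort VCF** — per variant a MAF uniform in the requested range, allele
  copies independent Bernoulli draws (Hardy–Weinberg), realised sparsely;
  no linkage disequilibrium, no population structure.
* **Gene model** — a few non-overlapping genes with 1–3 transcripts each.

All generators are pure functions of (parameters, seed); numbers are
formatted to 6 significant digits so fixture bytes are identical across
platforms.  Because the fixtures lack realistic score distributions, LD and
annotation correlation structure, passing tests demonstrate the mechanisms
(joins, rankings, packing, queries) — not calibration against real
databases.

## Problem sizes

The default test fixture uses two contigs of 600 and 400 bp (3,040 catalog
variants) and a 30-sample cohort — large enough that every query path,
partition and compression block boundary is exercised, small enough that
the whole suite runs in about a minute.  The compression measurement uses
20,000 samples × 2,000 rare variants (MAF ∈ [5e-5, 5e-4]); the monotonicity
spot-check repeats it at 1,000/5,000/20,000 samples with 200 variants.

## Known limitations

* Exact-key joins only: no fuzzy matching of differently normalised indels.
* The ranking population for aPCs is the store's SNV set; scores are not
  comparable across stores of different composition.
* Ploidy is fixed at 2; sample-major layouts and BCF output are not
  supported.
* The container is single-writer; appending a channel rewrites the file.
* XLS/RDS batch inputs are a plugin seam, not implemented in core.
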