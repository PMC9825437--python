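"""Deterministic synthetic inputs: variant catalogs, annotation source
tables, cohort VCFs and gene models.

These generators stand in for the genome-scale annotation database and the
cohort genotype data a production deployment would ingest.  Every generator
is a pure function of its parameters and a seed; text outputs use fixed
number formatting (6 significant digits) so fixture bytes are stable across
platforms and runs.

What the synthetic data emulates — and what it does not — is documented in
``docs/methods.md``: per-category numeric scores share a latent "functional
damage" factor plus independent noise (so aPC recovery is testable), allele
frequencies follow a heavy-tailed rare-variant distribution, ClinVar labels
are sparse, and genotypes obey Hardy-Weinberg equilibrium with no linkage
disequilibrium.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from varannot.registry_config import APC_COMPONENTS
from varannot.schema_store import KEY_COLUMN, SchemaRegistry
from varannot.variant_core import VariantKey

BASES = np.array(list("ACGT"))

#: default latent-factor model for per-category numeric scores
DEFAULT_LATENT_SD = 1.0
DEFAULT_NOISE_SD = 0.3

_CLINVAR_LEVELS = [
    "Pathogenic",
    "Likely_pathogenic",
    "Pathogenic/Likely_pathogenic",
    "Uncertain_significance",
    "Likely_benign",
    "Benign",
]
_GENCODE_CATEGORIES = ["exonic", "intronic", "intergenic", "UTR3", "UTR5", "splicing"]
_EXONIC_CATEGORIES = [
    "missense",
    "synonymous",
    "stopgain",
    "stoploss",
    "frameshift",
    "nonframeshift",
]


def _fmt(x: float) -> str:
    """Fixed 6-significant-digit formatting for byte-stable fixtures."""
    return f"{x:.6g}"


def gen_reference(contigs: list[tuple[str, int]], seed: int) -> dict[str, str]:
    """Seeded random reference sequence per contig."""
    rng = np.random.default_rng(seed)
    return {
        name: "".join(rng.choice(BASES, size=length)) for name, length in contigs
    }


def gen_catalog(
    contigs: list[tuple[str, int]],
    seed: int,
    n_indels_per_contig: int = 20,
) -> list[VariantKey]:
    """Every possible SNV on each contig plus a seeded sample of indels.

    For a contig of length L this yields exactly 3*L SNV keys (three
    alternate bases per reference base) against a seeded random reference,
    followed by ``n_indels_per_contig`` 1-5 bp insertions/deletions.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    reference = {
        name: "".join(rng.choice(BASES, size=length)) for name, length in contigs
    }
    keys: list[VariantKey] = []
    for name, length in contigs:
        ref_seq = reference[name]
        for pos0 in range(length):
            ref = ref_seq[pos0]
            for alt in "ACGT":
                if alt != ref:
                    keys.append(VariantKey(name, pos0 + 1, ref, alt))
        for _ in range(n_indels_per_contig):
            size = int(rng.integers(1, 6))
            if rng.random() < 0.5 and length > size + 1:  # deletion
                pos0 = int(rng.integers(0, length - size - 1))
                ref = ref_seq[pos0 : pos0 + size + 1]
                keys.append(VariantKey(name, pos0 + 1, ref, ref[0]))
            else:  # insertion
                pos0 = int(rng.integers(0, length - 1))
                anchor = ref_seq[pos0]
                ins = "".join(rng.choice(BASES, size=size))
                keys.append(VariantKey(name, pos0 + 1, anchor, anchor + ins))
    # coordinate-sorted, so cohort VCFs derived from the catalog are sorted
    contig_rank = {name: i for i, (name, _) in enumerate(contigs)}
    keys.sort(key=lambda k: (contig_rank[k.chrom], k.pos, k.ref, k.alt))
    return keys


def gen_annotation_tables(
    catalog: list[VariantKey],
    registry: SchemaRegistry,
    seed: int,
    latent_sd: float = DEFAULT_LATENT_SD,
    noise_sd: float = DEFAULT_NOISE_SD,
    rsid_fraction: float = 0.05,
    clinvar_fraction: float = 0.10,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Per-category source tables, an rsID alias table, and the latent truth.

    Numeric component scores of each aPC grouping are generated as one
    shared per-variant latent factor (SD ``latent_sd``) plus independent
    Gaussian noise (SD ``noise_sd``), so the first principal component of a
    grouping should recover the latent factor.  Allele frequencies follow
    ``10**Uniform(-5, -0.5)`` (heavy-tailed, mostly rare).  ClinVar labels
    are assigned to a sparse subset.  About ``rsid_fraction`` of variants
    receive rsID aliases (a few deliberately multi-allelic).

    Returns ``(tables_by_category, alias_table, latent_truth)`` where
    ``latent_truth`` holds the per-variant latent factor for each grouping
    (test-only ground truth, never an input to the store).
    """
    rng = np.random.default_rng(seed)
    keys = [str(k) for k in catalog]
    n = len(keys)

    latent = {
        grouping: rng.normal(0.0, latent_sd, size=n)
        for grouping in registry.apc_components
    }

    # numeric component fields: latent + noise, formatted to 6 sig digits
    component_values: dict[str, np.ndarray] = {}
    for grouping, comps in registry.apc_components.items():
        for comp in comps:
            component_values[comp] = latent[grouping] + rng.normal(0, noise_sd, size=n)

    af = 10 ** rng.uniform(-5, -0.5, size=n)

    tables: dict[str, pd.DataFrame] = {}
    for category in registry.categories:
        cols: dict[str, list] = {KEY_COLUMN: keys}
        for fname in registry.fields_in_category(category):
            fd = registry.by_name[fname]
            if fname.startswith("apc_"):
                continue  # computed downstream, never a source column
            if fname in component_values:
                cols[fname] = [_fmt(v) for v in component_values[fname]]
            elif fname == "rsid":
                continue  # lives in the alias table
            elif fname == "variant_type":
                cols[fname] = ["SNV" if k.is_snv else "indel" for k in catalog]
            elif fname == "variant_length":
                cols[fname] = [
                    _fmt(abs(len(k.alt) - len(k.ref)) or 1) for k in catalog
                ]
            elif fname == "gencode_category":
                cols[fname] = list(rng.choice(_GENCODE_CATEGORIES, size=n))
            elif fname == "gencode_exonic_category":
                cols[fname] = list(rng.choice(_EXONIC_CATEGORIES, size=n))
            elif fname.startswith("clinvar"):
                labels = np.full(n, "", dtype=object)
                hit = rng.random(n) < clinvar_fraction
                if fname == "clinvar_significance":
                    labels[hit] = rng.choice(_CLINVAR_LEVELS, size=int(hit.sum()))
                elif fname == "clinvar_variation_id":
                    labels[hit] = [f"VCV{int(i):09d}" for i in rng.integers(1, 10**6, size=int(hit.sum()))]
                else:
                    labels[hit] = rng.choice(["germline", "criteria_provided", "disease"], size=int(hit.sum()))
                cols[fname] = list(labels)
            elif fname.startswith(("af_", "ac_", "an_")):
                if fname == "af_distribution_bin":
                    continue  # derived display field, filled by the portal layer
                if fname.startswith("af_"):
                    jitter = af * 10 ** rng.normal(0, 0.1, size=n)
                    cols[fname] = [_fmt(min(v, 0.5)) for v in jitter]
                elif fname.startswith("ac_"):
                    cols[fname] = [_fmt(np.round(v * 10000)) for v in af]
                else:
                    cols[fname] = ["10000"] * n
            elif fd.phred_scaled:
                # marginal of a rank-based PHRED transform of a uniform score
                cols[fname] = [_fmt(v) for v in -10 * np.log10(rng.uniform(size=n))]
            elif fd.kind == "numeric":
                cols[fname] = [_fmt(v) for v in rng.normal(0, 1, size=n)]
            else:
                cols[fname] = [f"{fname}_{i % 7}" for i in range(n)]
        if len(cols) > 1:
            tables[category] = pd.DataFrame(cols)

    n_alias = max(1, int(round(rsid_fraction * n)))
    alias_idx = rng.choice(n, size=min(n_alias, n), replace=False)
    alias_rows = []
    next_rs = 1000
    for i in alias_idx:
        alias_rows.append({"rsid": f"rs{next_rs}", "key": keys[i]})
        next_rs += int(rng.integers(1, 50))
    # a couple of multi-allelic rsIDs: same rsid, sibling alt at same site
    by_site: dict[tuple[str, int], list[int]] = {}
    for i, k in enumerate(catalog):
        by_site.setdefault((k.chrom, k.pos), []).append(i)
    added = 0
    for row in alias_rows:
        c, p, *_ = row["key"].split("-")
        sibs = by_site.get((c, int(p)), [])
        for j in sibs:
            if keys[j] != row["key"]:
                alias_rows.append({"rsid": row["rsid"], "key": keys[j]})
                added += 1
                break
        if added >= 2:
            break
    aliases = pd.DataFrame(alias_rows, columns=["rsid", "key"])

    truth = pd.DataFrame({"key": keys, **{g: latent[g] for g in latent}})
    return tables, aliases, truth


def simulate_genotypes(
    n_variants: int,
    n_samples: int,
    maf_range: tuple[float, float],
    seed: int,
) -> np.ndarray:
    """Diploid biallelic genotypes under Hardy-Weinberg equilibrium.

    Each variant draws a minor-allele frequency uniformly from ``maf_range``
    (a subset of (0, 0.5]); every allele copy is an independent Bernoulli
    draw at that frequency, realised sparsely by drawing the alternate-allele
    count and placing carrier slots without replacement.  Returns a
    (2, samples, variants) int8 array of allele indices.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie in (0, 0.5], got {maf_range}")
    rng = np.random.default_rng(seed)
    two_n = 2 * n_samples
    g = np.zeros((2, n_samples, n_variants), dtype=np.int8)
    for j in range(n_variants):
        maf = rng.uniform(lo, hi)
        n_alt = rng.binomial(two_n, maf)
        if n_alt:
            slots = rng.choice(two_n, size=n_alt, replace=False)
            g[slots % 2, slots // 2, j] = 1
    return g


_GT_STRINGS = np.array(["0|0", "0|1", "1|0", "1|1"])


def gen_cohort_vcf(
    catalog: list[VariantKey],
    n_samples: int,
    maf_range: tuple[float, float],
    seed: int,
    path: str | Path,
    genotypes: np.ndarray | None = None,
) -> Path:
    """Write a plain-text diploid cohort VCF under Hardy-Weinberg equilibrium.

    Genotypes come from :func:`simulate_genotypes` (or a precomputed array
    of the same shape, which skips the simulation).  Deterministic per seed;
    bytes are stable across runs and platforms.
    """
    if genotypes is None:
        genotypes = simulate_genotypes(len(catalog), n_samples, maf_range, seed)
    path = Path(path)
    samples = [f"S{i:06d}" for i in range(n_samples)]
    contigs = sorted({k.chrom for k in catalog})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=varannot-fixtures\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j, k in enumerate(catalog):
            codes = genotypes[0, :, j].astype(np.int64) * 2 + genotypes[1, :, j]
            gts = _GT_STRINGS[codes]
            fh.write(
                f"{k.chrom}\t{k.pos}\t.\t{k.ref}\t{k.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
    return path


def gen_gene_model(
    contigs: list[tuple[str, int]],
    seed: int,
    path: str | Path,
    genes_per_contig: int = 3,
) -> Path:
    """Write a small GTF gene model: non-overlapping genes, 1-3 transcripts.

    Gene footprints lie within contig bounds; deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    path = Path(path)
    rows = []
    gene_no = 1
    for name, length in contigs:
        if length < 200:
            continue
        n_genes = min(genes_per_contig, max(1, length // 200))
        bounds = np.linspace(1, length, n_genes + 1).astype(int)
        for g in range(n_genes):
            lo, hi = int(bounds[g]), int(bounds[g + 1]) - 10
            if hi - lo < 100:
                continue
            g_start = lo + int(rng.integers(0, (hi - lo) // 4 + 1))
            g_end = g_start + int(rng.integers(50, max(51, (hi - lo) // 2)))
            g_end = min(g_end, hi)
            symbol = f"GENE{gene_no}"
            gene_no += 1
            attrs = f'gene_id "{symbol}"; gene_name "{symbol}";'
            rows.append((name, g_start, g_end, "gene", attrs))
            for t in range(int(rng.integers(1, 4))):
                t_start = g_start + int(rng.integers(0, max(1, (g_end - g_start) // 3)))
                t_end = g_end - int(rng.integers(0, max(1, (g_end - g_start) // 3)))
                if t_end <= t_start:
                    t_start, t_end = g_start, g_end
                t_attrs = attrs + f' transcript_id "{symbol}.{t + 1}";'
                rows.append((name, t_start, t_end, "transcript", t_attrs))
    with open(path, "w") as fh:
        for chrom, start, end, feature, attrs in rows:
            fh.write(
                f"{chrom}\tvarannot\t{feature}\t{start}\t{end}\t.\t+\t.\t{attrs}\n"
            )
    return path


def write_fixture_dir(
    out_dir: str | Path,
    seed: int,
    contigs: list[tuple[str, int]],
    n_samples: int = 100,
    maf_range: tuple[float, float] = (0.001, 0.3),
    latent_sd: float = DEFAULT_LATENT_SD,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> Path:
    """Materialise a complete fixture set under ``out_dir``.

    Layout: ``registry.yaml`` (the default schema), ``tables/<category>.csv``
    per annotation category, ``aliases.tsv``, ``genes.gtf``,
    ``cohort.vcf`` and ``truth.csv`` (latent factors, for tests only).
    """
    import yaml

    from varannot.registry_config import default_registry_config
    from varannot.schema_store import load_registry

    out = Path(out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    config = default_registry_config()
    with open(out / "registry.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    registry = load_registry(config)

    catalog = gen_catalog(contigs, seed)
    tables, aliases, truth = gen_annotation_tables(
        catalog, registry, seed + 1, latent_sd=latent_sd, noise_sd=noise_sd
    )
    for category, df in tables.items():
        slug = category.lower().replace(" ", "_")
        df.to_csv(out / "tables" / f"{slug}.csv", index=False)
    aliases.to_csv(out / "aliases.tsv", sep="\t", index=False)
    truth.to_csv(out / "truth.csv", index=False)
    gen_gene_model(contigs, seed + 2, out / "genes.gtf")
    gen_cohort_vcf(catalog, n_samples, maf_range, seed + 3, out / "cohort.vcf")
    return out


def load_fixture_store(fixture_dir: str | Path):
    """Rebuild the (store, registry, gene model) triple from a fixture dir."""
    from varannot.schema_store import GeneModel, build_store, load_registry

    fixture_dir = Path(fixture_dir)
    registry = load_registry(fixture_dir / "registry.yaml")
    tables = []
    for path in sorted((fixture_dir / "tables").glob("*.csv")):
        category = path.stem.replace("_", " ").title()
        # category name round-trips through the slug except for capitalisation
        match = [c for c in registry.categories if c.lower().replace(" ", "_") == path.stem]
        tables.append((match[0] if match else category, path))
    store = build_store(tables, registry, aliases=fixture_dir / "aliases.tsv")
    gene_model = GeneModel.from_gtf(fixture_dir / "genes.gtf")
    return store, registry, gene_model
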