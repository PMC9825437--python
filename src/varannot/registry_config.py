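"""The shipped default annotation schema.

160 annotation fields organised into 12 major functional categories and laid
out for display in 17 named blocks; a 20-field "essential" subset; the
32-column list used for region/gene variant tables; and the per-category
component groupings that feed the annotation principal components (aPCs).

Field names follow the sources a whole-genome annotation database would
integrate (CADD, GENCODE, ClinVar, gnomAD/TOPMed/1000G allele frequencies,
GERP/PhyloP/PhastCons conservation, ENCODE epigenetic marks, Umap/Bismap
mappability, ...).  Numeric fields use NaN as their missing sentinel; text,
categorical and flag fields use the empty string.
"""

from __future__ import annotations

CATEGORIES = [
    "Variant Category",
    "Allele Frequencies",
    "ClinVar",
    "Integrative Scores",
    "Protein Functions",
    "Conservation",
    "Epigenetics",
    "Chromatin States",
    "Local Nucleotide Diversity",
    "Mutation Density",
    "Mappability",
    "Proximity",
]

BLOCKS = [
    "Basic",
    "ClinVar",
    "Variant Category",
    "Overall AFs",
    "Ancestry-Specific AF",
    "Gender AF",
    "Integrative Score",
    "Protein Function",
    "Conservation",
    "Epigenetics",
    "Transcription Factors",
    "Chromatin States",
    "Local Nucleotide Diversity",
    "Mutation Density",
    "Mappability",
    "Proximity",
    "Histogram/Distribution",
]

# (name, kind, category, block, phred_scaled)
_F = []


def _add(names, kind, category, block, phred=False):
    for n in names:
        _F.append(
            {
                "name": n,
                "kind": kind,
                "category": category,
                "block": block,
                "phred_scaled": phred,
            }
        )


# Variant Category (8)
_add(["rsid"], "text", "Variant Category", "Basic")
_add(["variant_type"], "categorical", "Variant Category", "Basic")
_add(["variant_length"], "numeric", "Variant Category", "Basic")
_add(
    ["gencode_category", "gencode_exonic_category"],
    "categorical",
    "Variant Category",
    "Variant Category",
)
_add(["gencode_gene", "funseq_description"], "text", "Variant Category", "Variant Category")
_add(["af_distribution_bin"], "categorical", "Variant Category", "Histogram/Distribution")

# Allele Frequencies (24)
_add(
    [
        "af_1000g",
        "ac_1000g",
        "an_1000g",
        "af_topmed",
        "ac_topmed",
        "an_topmed",
        "af_gnomad",
        "ac_gnomad",
        "an_gnomad",
        "af_max",
    ],
    "numeric",
    "Allele Frequencies",
    "Overall AFs",
)
_add(
    [
        "af_1000g_afr",
        "af_1000g_amr",
        "af_1000g_eas",
        "af_1000g_eur",
        "af_1000g_sas",
        "af_gnomad_afr",
        "af_gnomad_amr",
        "af_gnomad_eas",
        "af_gnomad_nfe",
        "af_gnomad_sas",
    ],
    "numeric",
    "Allele Frequencies",
    "Ancestry-Specific AF",
)
_add(
    ["af_1000g_male", "af_1000g_female", "af_gnomad_male", "af_gnomad_female"],
    "numeric",
    "Allele Frequencies",
    "Gender AF",
)

# ClinVar (5)
_add(
    ["clinvar_significance", "clinvar_review_status", "clinvar_origin"],
    "categorical",
    "ClinVar",
    "ClinVar",
)
_add(["clinvar_disease_name", "clinvar_variation_id"], "text", "ClinVar", "ClinVar")

# Integrative Scores (14): named integrative scores plus the 8 aPCs
_add(["cadd_raw"], "numeric", "Integrative Scores", "Integrative Score")
_add(["cadd_phred"], "numeric", "Integrative Scores", "Integrative Score", phred=True)
_add(
    ["linsight", "fathmm_xf", "funseq_value", "aloft_value"],
    "numeric",
    "Integrative Scores",
    "Integrative Score",
)
APC_FIELDS = [
    "apc_conservation",
    "apc_epigenetics",
    "apc_protein_function",
    "apc_local_nucleotide_diversity",
    "apc_mutation_density",
    "apc_mappability",
    "apc_transcription_factor",
    "apc_chromatin_state",
]
_add(APC_FIELDS, "numeric", "Integrative Scores", "Integrative Score", phred=True)

# Protein Functions (12)
_add(
    [
        "polyphen2_hdiv_score",
        "polyphen2_hvar_score",
        "sift_score",
        "mutation_taster_score",
        "mutation_assessor_score",
        "provean_score",
        "metasvm_score",
        "revel_score",
        "grantham_score",
    ],
    "numeric",
    "Protein Functions",
    "Protein Function",
)
_add(
    ["polyphen2_hdiv_pred", "sift_pred"],
    "categorical",
    "Protein Functions",
    "Protein Function",
)
_add(["protein_domain"], "text", "Protein Functions", "Protein Function")

# Conservation (8) — exactly the eight standardized conservation scores
CONSERVATION_FIELDS = [
    "priphcons",
    "mamphcons",
    "verphcons",
    "priphylop",
    "mamphylop",
    "verphylop",
    "gerp_n",
    "gerp_s",
]
_add(CONSERVATION_FIELDS, "numeric", "Conservation", "Conservation")

# Epigenetics (30): 25 chromatin-accessibility/histone tracks + 5 TF signals
_EPI_TRACKS = [
    "dnase_seq",
    "atac_seq",
    "faire_seq",
    "mnase_seq",
    "h2afz",
    "h3k27ac",
    "h3k27me3",
    "h3k36me3",
    "h3k4me1",
    "h3k4me2",
    "h3k4me3",
    "h3k79me2",
    "h3k9ac",
    "h3k9me2",
    "h3k9me3",
    "h4k20me1",
    "h3k18ac",
    "h3k23ac",
    "h3k56ac",
    "h2bk5ac",
    "h2bk12ac",
    "h2bk15ac",
    "h2bk120ac",
    "h4k5ac",
    "total_rna_seq",
]
_add(_EPI_TRACKS, "numeric", "Epigenetics", "Epigenetics")
_TF_TRACKS = [
    "encode_tf_count",
    "ctcf_signal",
    "polr2a_signal",
    "ep300_signal",
    "tfbs_cluster_score",
]
_add(_TF_TRACKS, "numeric", "Epigenetics", "Transcription Factors")

# Chromatin States (25): per-state posterior tracks
_CHMM = [f"chmm_e{i}" for i in range(1, 26)]
_add(_CHMM, "numeric", "Chromatin States", "Chromatin States")

# Local Nucleotide Diversity (10)
_LND = [
    "nucdiv",
    "bstatistic",
    "recombination_rate",
    "gc_content",
    "cpg_content",
    "het_rate",
    "theta_w",
    "lnd_win_1kb",
    "lnd_win_10kb",
    "background_selection",
]
_add(_LND, "numeric", "Local Nucleotide Diversity", "Local Nucleotide Diversity")

# Mutation Density (9)
_MUTDENS = [
    "freq100bp",
    "rare100bp",
    "sngl100bp",
    "freq1000bp",
    "rare1000bp",
    "sngl1000bp",
    "freq10000bp",
    "rare10000bp",
    "sngl10000bp",
]
_add(_MUTDENS, "numeric", "Mutation Density", "Mutation Density")

# Mappability (8)
_MAPPABILITY = [
    "umap_k24",
    "umap_k36",
    "umap_k50",
    "umap_k100",
    "bismap_k24",
    "bismap_k36",
    "bismap_k50",
    "bismap_k100",
]
_add(_MAPPABILITY, "numeric", "Mappability", "Mappability")

# Proximity (7)
_add(
    [
        "dist_tss",
        "dist_tse",
        "min_dist_tss",
        "min_dist_tse",
        "upstream_gene_dist",
        "downstream_gene_dist",
    ],
    "numeric",
    "Proximity",
    "Proximity",
)
_add(["closest_gene"], "text", "Proximity", "Proximity")

ESSENTIAL_FIELDS = APC_FIELDS + [
    "cadd_phred",
    "linsight",
    "fathmm_xf",
    "funseq_value",
    "aloft_value",
    "polyphen2_hdiv_score",
    "sift_score",
    "gencode_category",
    "clinvar_significance",
    "af_topmed",
    "gerp_s",
    "nucdiv",
]

REGION_COLUMNS = [
    "rsid",
    "variant_type",
    "gencode_category",
    "gencode_exonic_category",
    "gencode_gene",
    "clinvar_significance",
    "af_1000g",
    "af_topmed",
    "af_gnomad",
    "cadd_phred",
    "linsight",
    "fathmm_xf",
    "funseq_value",
    "aloft_value",
    *APC_FIELDS,
    "polyphen2_hdiv_score",
    "sift_score",
    "gerp_s",
    "priphcons",
    "nucdiv",
    "bstatistic",
    "recombination_rate",
    "freq100bp",
    "umap_k24",
    "dist_tss",
]

# category grouping -> component fields feeding "apc_<grouping>"
APC_COMPONENTS = {
    "conservation": list(CONSERVATION_FIELDS),
    "epigenetics": [
        "dnase_seq",
        "atac_seq",
        "h3k27ac",
        "h3k27me3",
        "h3k36me3",
        "h3k4me1",
        "h3k4me3",
        "h3k9ac",
        "h3k9me3",
    ],
    "protein_function": [
        "polyphen2_hdiv_score",
        "polyphen2_hvar_score",
        "sift_score",
        "mutation_taster_score",
        "mutation_assessor_score",
        "provean_score",
        "metasvm_score",
        "revel_score",
    ],
    "local_nucleotide_diversity": [
        "nucdiv",
        "bstatistic",
        "recombination_rate",
        "gc_content",
        "cpg_content",
        "het_rate",
    ],
    "mutation_density": list(_MUTDENS),
    "mappability": list(_MAPPABILITY),
    "transcription_factor": list(_TF_TRACKS),
    "chromatin_state": list(_CHMM),
}


def default_registry_config() -> dict:
    """Return the shipped registry description document as a plain dict.

    The same structure round-trips through YAML; :func:`varannot.schema_store.
    load_registry` accepts either form.
    """
    return {
        "categories": list(CATEGORIES),
        "blocks": list(BLOCKS),
        "fields": [dict(f) for f in _F],
        "essential": list(ESSENTIAL_FIELDS),
        "region_columns": list(REGION_COLUMNS),
        "apc_components": {k: list(v) for k, v in APC_COMPONENTS.items()},
        "expected_counts": {"fields": 160, "categories": 12, "essential": 20},
    }
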