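"""Registry validation and store construction/queries against brute-force
oracles."""

import numpy as np
import pandas as pd
import pytest

from varannot.registry_config import default_registry_config
from varannot.schema_store import (
    GeneModel,
    RegistryError,
    StoreBuildError,
    build_store,
    load_registry,
)
from varannot.variant_core import VariantKey


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def test_default_registry_counts():
    registry = load_registry()
    counts = registry.counts()
    assert counts["fields"] == 160
    assert counts["categories"] == 12
    assert counts["essential"] == 20
    assert set(registry.essential) <= set(registry.field_names)


def test_conservation_grouping_has_eight_components():
    registry = load_registry()
    assert len(registry.apc_components["conservation"]) == 8


def test_region_column_list_has_32_entries():
    registry = load_registry()
    assert len(registry.region_columns) == 32


def test_block_layout_partitions_fields_into_17_blocks():
    registry = load_registry()
    layout = registry.block_layout()
    assert len(layout) == 17
    members = [f for fields in layout.values() for f in fields]
    assert sorted(members) == sorted(registry.field_names)


def test_duplicate_field_name_rejected():
    config = default_registry_config()
    config["fields"].append(dict(config["fields"][0]))
    config["expected_counts"] = None
    with pytest.raises(RegistryError, match="duplicate"):
        load_registry(config)


def test_unknown_category_rejected():
    config = default_registry_config()
    config["fields"][0]["category"] = "Nonexistent"
    with pytest.raises(RegistryError, match="unknown category"):
        load_registry(config)


def test_essential_field_must_exist_in_full_set():
    config = default_registry_config()
    config["essential"] = config["essential"] + ["no_such_field"]
    with pytest.raises(RegistryError, match="essential"):
        load_registry(config)


def test_registry_yaml_roundtrip(tmp_path):
    import yaml

    p = tmp_path / "registry.yaml"
    with open(p, "w") as fh:
        yaml.safe_dump(default_registry_config(), fh)
    registry = load_registry(p)
    assert registry.counts()["fields"] == 160


# ---------------------------------------------------------------------------
# store construction
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_registry():
    return load_registry()


def _mini_tables(registry, n=50, seed=3):
    """Three category tables over n keys + the expected outer-join frame."""
    rng = np.random.default_rng(seed)
    keys = [f"1-{i + 1}-A-C" for i in range(n - 5)] + [
        f"2-{i + 1}-CT-C" for i in range(5)
    ]
    cons = pd.DataFrame(
        {
            "variant_vcf": keys[:40],
            "gerp_s": rng.normal(size=40).round(4),
            "priphcons": rng.normal(size=40).round(4),
        }
    )
    clin = pd.DataFrame(
        {
            "variant_vcf": keys[20:],
            "clinvar_significance": ["Pathogenic"] * 10 + ["Benign"] * (n - 30),
        }
    )
    integ = pd.DataFrame(
        {"variant_vcf": keys, "cadd_phred": rng.uniform(0, 40, size=n).round(4)}
    )
    tables = [("Conservation", cons), ("ClinVar", clin), ("Integrative Scores", integ)]
    # independent oracle: pandas outer merge, no store machinery
    oracle = (
        cons.merge(clin, on="variant_vcf", how="outer")
        .merge(integ, on="variant_vcf", how="outer")
        .set_index("variant_vcf")
    )
    return keys, tables, oracle


def test_build_store_equals_outer_join_oracle(small_registry):
    keys, tables, oracle = _mini_tables(small_registry)
    store = build_store(tables, small_registry)
    assert len(store) == len(keys)
    for key in keys:
        rec = store.get_by_key(key)
        assert rec is not None
        for field in ("gerp_s", "priphcons", "cadd_phred"):
            expected = oracle.loc[key, field]
            got = rec.values[field]
            if pd.isna(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)
        expected_sig = oracle.loc[key, "clinvar_significance"]
        assert rec.values["clinvar_significance"] == (
            "" if pd.isna(expected_sig) else expected_sig
        )


def test_fields_never_assigned_keep_sentinel(small_registry):
    keys, tables, _ = _mini_tables(small_registry)
    store = build_store(tables[:1], small_registry)  # conservation only
    rec = store.get_by_key(tables[0][1]["variant_vcf"].iloc[0])
    assert np.isnan(rec.values["cadd_phred"])
    assert rec.values["clinvar_significance"] == ""
    assert rec.provenance == ("Conservation",)


def test_snv_indel_partition_routing(small_registry):
    keys, tables, _ = _mini_tables(small_registry)
    store = build_store(tables, small_registry)
    assert len(store.indel) == 5
    assert len(store.snv) == len(keys) - 5
    rec = store.get_by_key("2-1-CT-C")
    assert rec is not None and rec.key.ref == "CT"


def test_missing_key_column_rejected(small_registry):
    bad = pd.DataFrame({"key": ["1-1-A-C"], "gerp_s": [1.0]})
    with pytest.raises(StoreBuildError, match="variant_vcf"):
        build_store([("Conservation", bad)], small_registry)


def test_conflicting_values_abort_with_collision_listing(small_registry):
    t1 = pd.DataFrame({"variant_vcf": ["1-1-A-C"], "gerp_s": [1.0]})
    t2 = pd.DataFrame({"variant_vcf": ["1-1-A-C"], "gerp_s": [2.0]})
    with pytest.raises(StoreBuildError, match="1-1-A-C/gerp_s"):
        build_store([("Conservation", t1), ("Conservation", t2)], small_registry)


def test_unknown_table_column_rejected(small_registry):
    bad = pd.DataFrame({"variant_vcf": ["1-1-A-C"], "not_a_field": [1.0]})
    with pytest.raises(StoreBuildError, match="not_a_field"):
        build_store([("Conservation", bad)], small_registry)


# ---------------------------------------------------------------------------
# queries against the session fixture store
# ---------------------------------------------------------------------------

def test_get_by_key_exact_and_absent(store):
    key = store.keys()[7]
    rec = store.get_by_key(key)
    assert rec is not None and str(rec.key) == key
    assert store.get_by_key("22-999999-A-C") is None


def test_get_by_key_variantkey_object(store):
    key = store.keys()[0]
    c, p, r, a = key.split("-")
    assert store.get_by_key(VariantKey(c, int(p), r, a)) is not None


def test_get_by_rsid_multiallelic_and_unknown(store):
    multi = [rs for rs, keys in store._rsid_index.items() if len(keys) > 1]
    assert multi, "fixture should contain at least one multi-allelic rsID"
    recs = store.get_by_rsid(multi[0])
    assert len(recs) == len(store._rsid_index[multi[0]])
    sites = {(r.key.chrom, r.key.pos) for r in recs}
    assert len(sites) == 1  # same site, different alt alleles
    assert store.get_by_rsid("rs999999999") == []


def test_get_by_rsid_singleton(store):
    single = [rs for rs, keys in store._rsid_index.items() if len(keys) == 1]
    recs = store.get_by_rsid(single[0])
    assert len(recs) == 1


def _brute_force_range(store, chrom, start, end):
    hits = []
    for part in (store.snv, store.indel):
        for key, row in part.iterrows():
            if row["_chrom"] == chrom and start <= row["_pos"] <= end:
                hits.append(key)
    from varannot.schema_store import _sort_tuple

    return sorted(hits, key=_sort_tuple)


@pytest.mark.parametrize(
    "chrom, start, end",
    [("1", 1, 200), ("1", 150, 150), ("2", 1, 10**6), ("1", 9999, 10**6), ("2", 37, 215)],
)
def test_range_query_equals_linear_scan(store, chrom, start, end):
    got = [str(r.key) for r in store.get_by_range(chrom, start, end)]
    assert got == _brute_force_range(store, chrom, start, end)


def test_range_query_rejects_inverted_interval(store):
    with pytest.raises(ValueError):
        store.get_by_range("1", 100, 50)


def test_whole_contig_window_returns_everything_on_contig(store):
    got = store.get_by_range("2", 1, 10**9)
    expected = sum(
        (part["_chrom"] == "2").sum() for part in (store.snv, store.indel)
    )
    assert len(got) == expected


def test_gene_query_equals_range_over_footprint(store, gene_model):
    symbol = gene_model.symbols()[0]
    chrom, start, end = gene_model.footprint(symbol)
    by_gene = [str(r.key) for r in store.get_by_gene(symbol, gene_model)]
    by_range = [str(r.key) for r in store.get_by_range(chrom, start, end)]
    assert by_gene == by_range


def test_unknown_gene_symbol_reports_near_matches(store, gene_model):
    with pytest.raises(KeyError, match="GENE"):
        store.get_by_gene("GEN1", gene_model)


def test_footprint_is_min_start_max_end_of_transcripts():
    model = GeneModel({"TWO_TX": ("1", 5000, 9000)})
    assert model.footprint("TWO_TX") == ("1", 5000, 9000)


def test_gtf_footprint_spans_all_transcripts(tmp_path):
    gtf = tmp_path / "two_tx.gtf"
    gtf.write_text(
        '1\tsrc\tgene\t5000\t9000\t.\t+\t.\tgene_id "G1"; gene_name "G1";\n'
        '1\tsrc\ttranscript\t5000\t7000\t.\t+\t.\tgene_id "G1"; gene_name "G1"; transcript_id "G1.1";\n'
        '1\tsrc\ttranscript\t6500\t9000\t.\t+\t.\tgene_id "G1"; gene_name "G1"; transcript_id "G1.2";\n'
    )
    model = GeneModel.from_gtf(gtf)
    assert model.footprint("G1") == ("1", 5000, 9000)


def test_every_source_key_lands_in_exactly_one_partition(store, fixture_dir):
    import pandas as pd

    source_keys = set()
    for path in (fixture_dir / "tables").glob("*.csv"):
        source_keys |= set(pd.read_csv(path, usecols=["variant_vcf"])["variant_vcf"])
    snv_keys, indel_keys = set(store.snv.index), set(store.indel.index)
    assert snv_keys | indel_keys == source_keys
    assert not (snv_keys & indel_keys)
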