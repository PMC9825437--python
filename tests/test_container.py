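"""Annotated container: 2-bit packing, lossless round trips across codecs
and block sizes, random access, channel append, validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from varannot.agds_container import (
    AnnotatedContainer,
    CompressionSpec,
    ContainerError,
    pack_genotypes,
    unpack_genotypes,
    write_container,
)
from varannot.variant_core import VariantKey


def _keys(n, chrom="1"):
    return [VariantKey(chrom, i + 1, "A", "C") for i in range(n)]


def _random_genotypes(rng, n_samples, n_variants, p_missing=0.05, p_multi=0.02):
    g = rng.integers(0, 3, size=(2, n_samples, n_variants)).astype(np.int16)
    g[rng.random(g.shape) < p_missing] = -1
    g[rng.random(g.shape) < p_multi] = rng.integers(3, 7)
    return g


# ---------------------------------------------------------------------------
# 2-bit packing
# ---------------------------------------------------------------------------

def test_pack_four_slots_one_byte():
    # slots in order (variant 0: sample0 p0,p1; sample1 p0,p1) = [0,1,2,3]
    g = np.array([[[0], [2]], [[1], [3]]])
    packed, index, overflow = pack_genotypes(g)
    assert packed[0] == 0xE4  # binary 11 10 01 00, first slot in the LSBs
    assert overflow == [(0, 1, 1, 3)]
    assert list(index) == [1]


def test_pack_all_missing_column_uses_escape_without_overflow():
    g = np.full((2, 3, 1), -1)
    packed, index, overflow = pack_genotypes(g)
    assert overflow == []
    assert list(index) == [0]
    assert np.array_equal(unpack_genotypes(packed, 3, 1), g)


def test_pack_allele_index_5_goes_to_overflow():
    g = np.zeros((2, 2, 1), dtype=int)
    g[1, 0, 0] = 5
    packed, index, overflow = pack_genotypes(g)
    assert overflow == [(0, 0, 1, 5)]
    assert list(index) == [1]
    assert np.array_equal(unpack_genotypes(packed, 2, 1, overflow), g)


@settings(derandomize=True, max_examples=60)
@given(
    n_samples=st.integers(1, 8),
    n_variants=st.integers(0, 12),
    seed=st.integers(0, 1000),
)
def test_pack_unpack_roundtrip(n_samples, n_variants, seed):
    rng = np.random.default_rng(seed)
    g = _random_genotypes(rng, n_samples, n_variants)
    packed, _, overflow = pack_genotypes(g)
    assert np.array_equal(unpack_genotypes(packed, n_samples, n_variants, overflow), g)


# ---------------------------------------------------------------------------
# container round trips
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("codec", ["lzma", "zlib", "none"])
@pytest.mark.parametrize("block_size", [1, 7, 1000])
def test_container_roundtrip_across_codecs_and_blocks(tmp_path, codec, block_size):
    rng = np.random.default_rng(42)
    n_s, n_v = 5, 23
    g = _random_genotypes(rng, n_s, n_v)
    keys = _keys(n_v)
    ann = {
        "score": ("float64", list(rng.normal(size=n_v))),
        "label": ("text", [f"L{i}" if i % 3 else "" for i in range(n_v)]),
    }
    path = tmp_path / f"c_{codec}_{block_size}.agds"
    write_container(path, [f"S{i}" for i in range(n_s)], keys, g, ann, CompressionSpec(codec, block_size))
    c = AnnotatedContainer(path)
    assert c.sample_ids == [f"S{i}" for i in range(n_s)]
    assert c.variant_keys() == [str(k) for k in keys]
    assert np.array_equal(c.read_genotypes(), g)
    back = c.read_annotations(["score", "label"])
    assert np.allclose(back["score"], ann["score"][1])
    assert back["label"] == ann["label"][1]


def test_codecs_and_block_sizes_decode_identically(tmp_path):
    rng = np.random.default_rng(3)
    g = _random_genotypes(rng, 4, 50)
    keys = _keys(50)
    contents = []
    for codec in ("lzma", "zlib"):
        for bs in (7, 1000):
            p = tmp_path / f"x_{codec}_{bs}.agds"
            write_container(p, ["a", "b", "c", "d"], keys, g, None, CompressionSpec(codec, bs))
            c = AnnotatedContainer(p)
            contents.append((c.variant_keys(), c.read_genotypes().tolist()))
    assert all(x == contents[0] for x in contents[1:])


def test_selection_equals_full_decode_slice(tmp_path):
    rng = np.random.default_rng(9)
    g = _random_genotypes(rng, 6, 40)
    p = tmp_path / "sel.agds"
    write_container(p, [f"S{i}" for i in range(6)], _keys(40), g, None, CompressionSpec("zlib", 8))
    c = AnnotatedContainer(p)
    full = c.read_genotypes()
    sel = c.read_genotypes(variants=[10, 11, 12], samples=[0, 5])
    assert np.array_equal(sel, full[:, [0, 5], :][:, :, [10, 11, 12]])


def test_selection_touches_only_overlapping_blocks(tmp_path):
    rng = np.random.default_rng(10)
    g = _random_genotypes(rng, 3, 64)
    p = tmp_path / "blocks.agds"
    write_container(p, ["a", "b", "c"], _keys(64), g, None, CompressionSpec("zlib", 8))
    c = AnnotatedContainer(p)
    c.decompress_count = 0
    c.read_genotypes(variants=[17, 18])  # one 8-variant block
    assert c.decompress_count <= 1
    c.decompress_count = 0
    c.read_genotypes(variants=[7, 8])  # straddles two blocks
    assert c.decompress_count <= 2


def test_region_selector_equals_index_selector(tmp_path):
    g = _random_genotypes(np.random.default_rng(4), 2, 30)
    p = tmp_path / "reg.agds"
    write_container(p, ["a", "b"], _keys(30), g, None, CompressionSpec("zlib", 10))
    c = AnnotatedContainer(p)
    by_region = c.read_genotypes(region=("1", 5, 9))
    by_index = c.read_genotypes(variants=[4, 5, 6, 7, 8])
    assert np.array_equal(by_region, by_index)


def test_empty_selection_has_correct_shape(tmp_path):
    g = _random_genotypes(np.random.default_rng(5), 3, 10)
    p = tmp_path / "empty.agds"
    write_container(p, ["a", "b", "c"], _keys(10), g, None)
    c = AnnotatedContainer(p)
    assert c.read_genotypes(variants=[]).shape == (2, 3, 0)


def test_out_of_range_selectors_rejected(tmp_path):
    g = _random_genotypes(np.random.default_rng(6), 3, 10)
    p = tmp_path / "oob.agds"
    write_container(p, ["a", "b", "c"], _keys(10), g, None)
    c = AnnotatedContainer(p)
    with pytest.raises(IndexError):
        c.read_genotypes(variants=[10])
    with pytest.raises(IndexError):
        c.read_genotypes(samples=[3])


def test_unknown_annotation_field_lists_available(tmp_path):
    p = tmp_path / "fields.agds"
    write_container(p, None, _keys(5), None, {"score": ("float64", [1.0] * 5)})
    c = AnnotatedContainer(p)
    with pytest.raises(KeyError, match="score"):
        c.read_annotations(["xyz"])


def test_misaligned_annotation_stream_aborts(tmp_path):
    with pytest.raises(ContainerError, match="3 values"):
        write_container(
            tmp_path / "bad.agds", None, _keys(5), None, {"s": ("float64", [1.0] * 3)}
        )


def test_misaligned_genotype_stream_aborts(tmp_path):
    g = np.zeros((2, 3, 4), dtype=int)
    with pytest.raises(ContainerError, match="variant dimension"):
        write_container(tmp_path / "bad2.agds", ["a", "b", "c"], _keys(5), g, None)


# ---------------------------------------------------------------------------
# channel append
# ---------------------------------------------------------------------------

def test_add_channel_retrievable_and_others_untouched(tmp_path):
    import hashlib

    rng = np.random.default_rng(12)
    g = _random_genotypes(rng, 3, 20)
    p = tmp_path / "add.agds"
    write_container(
        p, ["a", "b", "c"], _keys(20), g, {"base": ("float64", list(rng.normal(size=20)))}
    )
    c = AnnotatedContainer(p)
    base_before = c.read_annotations(["base"])["base"]
    gt_checksum = hashlib.sha256(c.read_genotypes().tobytes()).hexdigest()
    c.add_annotation_channel("my_score", "float64", list(range(20)))
    assert c.read_annotations(["my_score"])["my_score"] == [float(i) for i in range(20)]
    assert c.read_annotations(["base"])["base"] == base_before
    assert hashlib.sha256(c.read_genotypes().tobytes()).hexdigest() == gt_checksum


def test_add_channel_survives_reopen(tmp_path):
    p = tmp_path / "reopen.agds"
    write_container(p, None, _keys(6), None, {"a": ("text", list("abcdef"))})
    AnnotatedContainer(p).add_annotation_channel("b", "text", list("uvwxyz"))
    fresh = AnnotatedContainer(p)
    assert fresh.read_annotations(["b"])["b"] == list("uvwxyz")
    assert fresh.read_annotations(["a"])["a"] == list("abcdef")


def test_add_channel_rejects_wrong_length_and_duplicate(tmp_path):
    p = tmp_path / "dup.agds"
    write_container(p, None, _keys(4), None, {"a": ("float64", [0.0] * 4)})
    c = AnnotatedContainer(p)
    with pytest.raises(ContainerError, match="4 variants"):
        c.add_annotation_channel("b", "float64", [0.0] * 3)
    with pytest.raises(ContainerError, match="already exists"):
        c.add_annotation_channel("a", "float64", [0.0] * 4)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def test_fresh_container_validates_clean(tmp_path):
    g = _random_genotypes(np.random.default_rng(1), 4, 30)
    p = tmp_path / "ok.agds"
    write_container(p, list("abcd"), _keys(30), g, {"s": ("float64", [0.5] * 30)})
    report = AnnotatedContainer(p).validate()
    assert all(entry["pass"] for entry in report.values())


def test_truncated_block_flagged_not_raised(tmp_path):
    g = _random_genotypes(np.random.default_rng(2), 4, 30)
    p = tmp_path / "corrupt.agds"
    write_container(p, list("abcd"), _keys(30), g, None, CompressionSpec("zlib", 10))
    c = AnnotatedContainer(p)
    # truncate the file mid-way through the last block
    data = p.read_bytes()
    p.write_bytes(data[:-5])
    report = AnnotatedContainer(p).validate()
    assert not report["block_decode"]["pass"]


def test_sites_only_container_skips_genotype_checks(tmp_path):
    p = tmp_path / "sites.agds"
    write_container(p, None, _keys(8), None, {"s": ("text", ["x"] * 8)})
    c = AnnotatedContainer(p)
    assert not c.has_genotypes
    report = c.validate()
    assert report["genotype_index"]["pass"]
    assert "skipped" in report["genotype_index"]["detail"]
    with pytest.raises(ContainerError, match="sites-only"):
        c.read_genotypes()


# ---------------------------------------------------------------------------
# compression behaviour on rare-variant cohorts
# ---------------------------------------------------------------------------

def test_compression_ratio_grows_with_sample_count(tmp_path):
    """On mostly-hom-ref cohorts the VCF:container ratio increases with n."""
    import os

    from varannot.fixture_gen import gen_cohort_vcf, simulate_genotypes

    ratios = []
    for n in (1000, 5000, 20000):
        keys = _keys(200)
        g = simulate_genotypes(200, n, (5e-5, 5e-4), seed=123)
        vcf = tmp_path / f"cohort_{n}.vcf"
        gen_cohort_vcf(keys, n, (5e-5, 5e-4), 123, vcf, genotypes=g)
        agds = tmp_path / f"cohort_{n}.agds"
        write_container(
            agds, [f"S{i:06d}" for i in range(n)], keys, g.astype(np.int16), None,
            CompressionSpec("lzma", 1024),
        )
        ratios.append(os.path.getsize(vcf) / os.path.getsize(agds))
    assert ratios[0] < ratios[1] < ratios[2]
    assert ratios[2] > 100  # container bytes << VCF text bytes
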