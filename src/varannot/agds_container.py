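"""Annotated genomic container: genotypes + aligned annotation channels.

One ``.agds`` file holds, for a set of variants in a fixed order:

* parallel variant arrays (chrom, pos, ref, alt);
* an optional diploid genotype channel stored as a 2-bit packed array with
  logical dimensions (ploidy=2, samples, variants), an index vector marking
  variants that carry escape (overflow) slots, and an explicit overflow list
  for allele indices that do not fit in 2 bits;
* one annotation channel per registered field, text channels stored as
  length-prefixed payloads.

Every channel is cut into blocks of ``block_size`` variants and each block is
compressed independently (LZMA, zlib, or stored raw), so reading a selection
decompresses only the blocks it overlaps.  The container counts block
decompressions (``decompress_count``) so that the random-access contract is
observable.

This is a re-implementation of the *logical* annotated-GDS layout; the
physical byte layout is this package's own (documented in
``docs/methods.md``) and is not binary-compatible with CoreArray GDS.

Physical layout::

    magic  b"AGDS\\x01\\n"
    u64le  compressed-header length H
    bytes  zlib-compressed JSON header (H bytes)
    bytes  data blocks, at offsets recorded in the header directory

The header records the codec, block size, counts, the channel directory
(per-block ``[offset, compressed_len, raw_len]`` relative to the data
start), and the genotype overflow list.
"""

from __future__ import annotations

import json
import lzma
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

MAGIC = b"AGDS\x01\n"
FORMAT_VERSION = 1
MISSING_GT = -1

_CODECS = ("lzma", "zlib", "none")


class ContainerError(ValueError):
    pass


@dataclass(frozen=True)
class CompressionSpec:
    """Codec and block granularity used for every channel of a container."""

    codec: str = "lzma"
    block_size: int = 1024

    def __post_init__(self):
        if self.codec not in _CODECS:
            raise ContainerError(f"unknown codec {self.codec!r}; supported: {_CODECS}")
        if self.block_size < 1:
            raise ContainerError("block_size must be >= 1")


def _compress(codec: str, raw: bytes) -> bytes:
    if codec == "lzma":
        return lzma.compress(raw, preset=6)
    if codec == "zlib":
        return zlib.compress(raw, 6)
    return raw


def _decompress(codec: str, data: bytes) -> bytes:
    if codec == "lzma":
        return lzma.decompress(data)
    if codec == "zlib":
        return zlib.decompress(data)
    return data


# ---------------------------------------------------------------------------
# 2-bit genotype packing
# ---------------------------------------------------------------------------

def pack_genotypes(genotypes: np.ndarray):
    """Pack a (2, samples, variants) allele-index array into 2-bit slots.

    Missing genotypes are marked ``-1``.  Slot order is variant-major, then
    sample, then ploidy fastest; within a byte the first slot occupies the
    least-significant bit pair.  Allele indices 0-2 are stored directly;
    the escape code 3 stands for "missing or >= 3", disambiguated by the
    returned overflow list of ``(variant, sample, ploidy_slot, value)``
    entries.  The per-variant index vector is 1 where a variant carries
    overflow entries and 0 otherwise.

    Returns ``(packed_bytes, index_vector, overflow_list)``.
    """
    g = np.asarray(genotypes)
    if g.ndim != 3 or g.shape[0] != 2:
        raise ContainerError(
            f"genotypes must have shape (2, samples, variants), got {g.shape}"
        )
    if g.size and (g[g != MISSING_GT] < 0).any():
        raise ContainerError("allele indices must be >= 0 or the missing marker -1")
    _, n_samples, n_variants = g.shape
    # slot order: variant-major, sample, ploidy fastest
    slots = np.transpose(g, (2, 1, 0)).reshape(-1).astype(np.int64)
    codes = slots.copy()
    codes[(slots == MISSING_GT) | (slots >= 3)] = 3
    codes = codes.astype(np.uint8)

    over_idx = np.nonzero(slots >= 3)[0]
    overflow = []
    for flat in over_idx:
        v, rem = divmod(int(flat), 2 * n_samples)
        s, p = divmod(rem, 2)
        overflow.append((v, s, p, int(slots[flat])))

    index_vector = np.zeros(n_variants, dtype=np.uint8)
    for v, _, _, _ in overflow:
        index_vector[v] = 1

    pad = (-len(codes)) % 4
    if pad:
        codes = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)])
    quads = codes.reshape(-1, 4)
    packed = (
        quads[:, 0] | (quads[:, 1] << 2) | (quads[:, 2] << 4) | (quads[:, 3] << 6)
    ).astype(np.uint8)
    return packed.tobytes(), index_vector, overflow


def unpack_genotypes(
    packed: bytes,
    n_samples: int,
    n_variants: int,
    overflow: Sequence[tuple[int, int, int, int]] = (),
) -> np.ndarray:
    """Inverse of :func:`pack_genotypes`; returns int16 with -1 for missing."""
    raw = np.frombuffer(packed, dtype=np.uint8)
    n_slots = 2 * n_samples * n_variants
    codes = np.empty(len(raw) * 4, dtype=np.int16)
    codes[0::4] = raw & 0b11
    codes[1::4] = (raw >> 2) & 0b11
    codes[2::4] = (raw >> 4) & 0b11
    codes[3::4] = (raw >> 6) & 0b11
    codes = codes[:n_slots]
    codes[codes == 3] = MISSING_GT
    for v, s, p, value in overflow:
        codes[(v * n_samples + s) * 2 + p] = value
    return np.transpose(codes.reshape(n_variants, n_samples, 2), (2, 1, 0))


# ---------------------------------------------------------------------------
# channel codecs
# ---------------------------------------------------------------------------

_NUMERIC_DTYPES = {"float64": "<f8", "int64": "<i8", "uint8": "<u1"}


def _encode_values(kind: str, values) -> bytes:
    if kind in _NUMERIC_DTYPES:
        return np.asarray(values).astype(_NUMERIC_DTYPES[kind]).tobytes()
    if kind == "text":
        encoded = [("" if v is None else str(v)).encode("utf-8") for v in values]
        lengths = np.array([len(e) for e in encoded], dtype="<u4")
        return lengths.tobytes() + b"".join(encoded)
    raise ContainerError(f"unknown channel kind {kind!r}")


def _decode_values(kind: str, raw: bytes, count: int):
    if kind in _NUMERIC_DTYPES:
        arr = np.frombuffer(raw, dtype=_NUMERIC_DTYPES[kind])
        if len(arr) != count:
            raise ContainerError(f"channel block holds {len(arr)} values, expected {count}")
        return arr.copy()
    if kind == "text":
        lengths = np.frombuffer(raw[: 4 * count], dtype="<u4")
        payload = raw[4 * count:]
        if int(lengths.sum()) != len(payload):
            raise ContainerError("text block payload length mismatch")
        out, off = [], 0
        for ln in lengths:
            out.append(payload[off : off + int(ln)].decode("utf-8"))
            off += int(ln)
        return out
    raise ContainerError(f"unknown channel kind {kind!r}")


def _blocks_of(n: int, block_size: int) -> list[tuple[int, int]]:
    return [(lo, min(lo + block_size, n)) for lo in range(0, n, block_size)]


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------

def write_container(
    path: str | Path,
    sample_ids: Sequence[str] | None,
    variants: Sequence,
    genotypes: np.ndarray | None = None,
    annotations: Mapping[str, tuple[str, Sequence]] | None = None,
    compression: CompressionSpec = CompressionSpec(),
) -> "AnnotatedContainer":
    """Write a container file and return it opened.

    ``variants`` is an ordered sequence of keys (anything with ``chrom``,
    ``pos``, ``ref``, ``alt`` attributes, or ``chrom-pos-ref-alt`` strings).
    ``genotypes`` is an optional (2, samples, variants) allele-index array
    with -1 for missing; omit it for a sites-only container.  ``annotations``
    maps field name to ``(kind, values)`` with kind ``float64`` or ``text``
    and one value per variant.
    """
    path = Path(path)
    n_variants = len(variants)
    keys = []
    for v in variants:
        if isinstance(v, str):
            c, p, r, a = v.split("-")
            keys.append((c, int(p), r, a))
        else:
            keys.append((v.chrom, int(v.pos), v.ref, v.alt))

    channels: list[tuple[str, str, object, int]] = []  # (name, kind, values, length)
    if sample_ids is not None:
        channels.append(("sample_ids", "text", [str(s) for s in sample_ids], len(sample_ids)))
    channels.append(("variant_chrom", "text", [k[0] for k in keys], n_variants))
    channels.append(
        ("variant_pos", "int64", np.array([k[1] for k in keys], dtype=np.int64), n_variants)
    )
    channels.append(("variant_ref", "text", [k[2] for k in keys], n_variants))
    channels.append(("variant_alt", "text", [k[3] for k in keys], n_variants))

    overflow: list[tuple[int, int, int, int]] = []
    n_samples = None
    if genotypes is not None:
        g = np.asarray(genotypes)
        if g.ndim != 3 or g.shape[0] != 2:
            raise ContainerError(
                f"genotypes must have shape (2, samples, variants), got {g.shape}"
            )
        if g.shape[2] != n_variants:
            raise ContainerError(
                f"genotype variant dimension {g.shape[2]} does not match "
                f"{n_variants} variants"
            )
        n_samples = int(g.shape[1])
        if sample_ids is not None and len(sample_ids) != n_samples:
            raise ContainerError(
                f"{len(sample_ids)} sample IDs for {n_samples} genotype columns"
            )
        channels.append(("genotype", "genotype", g, n_variants))

    for name, (kind, values) in (annotations or {}).items():
        if kind not in ("float64", "text"):
            raise ContainerError(f"annotation channel kind must be float64 or text, got {kind!r}")
        if len(values) != n_variants:
            raise ContainerError(
                f"annotation channel {name!r} has {len(values)} values for "
                f"{n_variants} variants"
            )
        channels.append((name, kind, values, n_variants))

    bs = compression.block_size
    directory: dict[str, dict] = {}
    order: list[str] = []
    payload = bytearray()
    genotype_index = None
    for name, kind, values, length in channels:
        entries = []
        if kind == "genotype":
            g = values
            idx_parts = []
            for lo, hi in _blocks_of(length, bs):
                packed, idx, over = pack_genotypes(g[:, :, lo:hi])
                idx_parts.append(idx)
                overflow.extend((v + lo, s, p, val) for v, s, p, val in over)
                comp = _compress(compression.codec, packed)
                entries.append([len(payload), len(comp), len(packed)])
                payload.extend(comp)
            genotype_index = (
                np.concatenate(idx_parts) if idx_parts else np.zeros(0, dtype=np.uint8)
            )
        else:
            for lo, hi in _blocks_of(length, bs):
                raw = _encode_values(kind, values[lo:hi])
                comp = _compress(compression.codec, raw)
                entries.append([len(payload), len(comp), len(raw)])
                payload.extend(comp)
        directory[name] = {"kind": kind, "n": length, "blocks": entries}
        order.append(name)

    if genotype_index is not None:
        entries = []
        for lo, hi in _blocks_of(n_variants, bs):
            raw = _encode_values("uint8", genotype_index[lo:hi])
            comp = _compress(compression.codec, raw)
            entries.append([len(payload), len(comp), len(raw)])
            payload.extend(comp)
        directory["genotype_index"] = {"kind": "uint8", "n": n_variants, "blocks": entries}
        order.append("genotype_index")

    annotation_names = list((annotations or {}).keys())
    header = {
        "version": FORMAT_VERSION,
        "codec": compression.codec,
        "block_size": bs,
        "n_variants": n_variants,
        "n_samples": n_samples,
        "has_genotypes": genotypes is not None,
        "annotation_fields": annotation_names,
        "overflow": [list(e) for e in overflow],
        "channel_order": order,
        "channels": directory,
    }
    _write_file(path, header, bytes(payload))
    return AnnotatedContainer(path)


def _write_file(path: Path, header: dict, payload: bytes) -> None:
    header_bytes = zlib.compress(json.dumps(header, separators=(",", ":")).encode(), 9)
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(len(header_bytes).to_bytes(8, "little"))
        fh.write(header_bytes)
        fh.write(payload)


# ---------------------------------------------------------------------------
# reader
# ---------------------------------------------------------------------------

class AnnotatedContainer:
    """Random-access reader (and in-place extender) of a ``.agds`` file.

    ``decompress_count`` counts block decompressions since the last reset and
    is the hook by which the only-touch-overlapping-blocks contract is
    verified.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        with open(self.path, "rb") as fh:
            magic = fh.read(len(MAGIC))
            if magic != MAGIC:
                raise ContainerError(f"{self.path} is not an annotated container")
            hlen = int.from_bytes(fh.read(8), "little")
            self.header = json.loads(zlib.decompress(fh.read(hlen)))
        self._data_start = len(MAGIC) + 8 + hlen
        self.decompress_count = 0

    # -- basic properties ---------------------------------------------------

    @property
    def codec(self) -> str:
        return self.header["codec"]

    @property
    def block_size(self) -> int:
        return self.header["block_size"]

    @property
    def n_variants(self) -> int:
        return self.header["n_variants"]

    @property
    def n_samples(self) -> int | None:
        return self.header["n_samples"]

    @property
    def has_genotypes(self) -> bool:
        return self.header["has_genotypes"]

    @property
    def annotation_fields(self) -> list[str]:
        return list(self.header["annotation_fields"])

    @property
    def sample_ids(self) -> list[str] | None:
        if "sample_ids" not in self.header["channels"]:
            return None
        return self._read_channel_blocks("sample_ids")

    def variant_keys(self) -> list[str]:
        chrom = self._read_channel_blocks("variant_chrom")
        pos = self._read_channel_blocks("variant_pos")
        ref = self._read_channel_blocks("variant_ref")
        alt = self._read_channel_blocks("variant_alt")
        return [f"{c}-{int(p)}-{r}-{a}" for c, p, r, a in zip(chrom, pos, ref, alt)]

    # -- block IO ------------------------------------------------------------

    def _read_block(self, name: str, block_idx: int):
        ch = self.header["channels"][name]
        off, clen, rawlen = ch["blocks"][block_idx]
        with open(self.path, "rb") as fh:
            fh.seek(self._data_start + off)
            comp = fh.read(clen)
        raw = _decompress(self.codec, comp)
        self.decompress_count += 1
        if len(raw) != rawlen:
            raise ContainerError(
                f"block {block_idx} of channel {name!r} decoded to {len(raw)} "
                f"bytes, expected {rawlen}"
            )
        lo = block_idx * self.block_size
        hi = min(lo + self.block_size, ch["n"])
        if ch["kind"] == "genotype":
            over = [
                (v - lo, s, p, val)
                for v, s, p, val in self.header["overflow"]
                if lo <= v < hi
            ]
            return unpack_genotypes(raw, self.n_samples, hi - lo, over)
        return _decode_values(ch["kind"], raw, hi - lo)

    def _read_channel_blocks(self, name: str, blocks: Sequence[int] | None = None):
        ch = self.header["channels"][name]
        if blocks is None:
            blocks = range(len(ch["blocks"]))
        parts = [self._read_block(name, b) for b in blocks]
        if not parts:
            return np.zeros(0) if ch["kind"] in _NUMERIC_DTYPES else []
        if ch["kind"] in _NUMERIC_DTYPES:
            return np.concatenate(parts)
        if ch["kind"] == "genotype":
            return np.concatenate(parts, axis=2)
        out = []
        for p in parts:
            out.extend(p)
        return out

    # -- selectors -----------------------------------------------------------

    def _resolve_variant_selector(self, selector, region) -> np.ndarray:
        if region is not None:
            chrom, start, end = region
            chroms = np.asarray(self._read_channel_blocks("variant_chrom"), dtype=object)
            pos = self._read_channel_blocks("variant_pos")
            mask = (chroms == str(chrom)) & (pos >= start) & (pos <= end)
            return np.nonzero(mask)[0]
        if selector is None:
            return np.arange(self.n_variants)
        idx = np.asarray(selector, dtype=np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_variants):
            raise IndexError(
                f"variant selector out of range [0, {self.n_variants})"
            )
        return idx

    def read_genotypes(
        self,
        variants: Sequence[int] | None = None,
        samples: Sequence[int] | None = None,
        region: tuple[str, int, int] | None = None,
    ) -> np.ndarray:
        """Allele-index sub-array (2, selected samples, selected variants).

        ``variants`` is an index set (container order preserved in the
        output) or ``None`` for all; ``region`` is an alternative
        ``(chrom, start, end)`` selector.  Only blocks overlapping the
        selection are decompressed.
        """
        if not self.has_genotypes:
            raise ContainerError("container has no genotype channel (sites-only)")
        idx = self._resolve_variant_selector(variants, region)
        n_samp = self.n_samples
        samp_idx = (
            np.arange(n_samp) if samples is None else np.asarray(samples, dtype=np.int64)
        )
        if samp_idx.size and (samp_idx.min() < 0 or samp_idx.max() >= n_samp):
            raise IndexError(f"sample selector out of range [0, {n_samp})")
        out = np.empty((2, len(samp_idx), len(idx)), dtype=np.int16)
        if len(idx) == 0:
            return out
        blocks_needed = sorted(set(int(i) // self.block_size for i in idx))
        cache = {b: self._read_block("genotype", b) for b in blocks_needed}
        for j, v in enumerate(idx):
            b, within = divmod(int(v), self.block_size)
            out[:, :, j] = cache[b][:, samp_idx, within]
        return out

    def read_annotations(
        self,
        fields: Sequence[str],
        variants: Sequence[int] | None = None,
        region: tuple[str, int, int] | None = None,
    ) -> dict[str, list]:
        """Per-field value lists aligned to the selected variants."""
        available = self.annotation_fields
        for f in fields:
            if f not in self.header["channels"] or f not in available:
                raise KeyError(
                    f"unknown annotation channel {f!r}; available: {available}"
                )
        idx = self._resolve_variant_selector(variants, region)
        out: dict[str, list] = {}
        for f in fields:
            blocks_needed = sorted(set(int(i) // self.block_size for i in idx))
            cache = {b: self._read_block(f, b) for b in blocks_needed}
            vals = []
            for v in idx:
                b, within = divmod(int(v), self.block_size)
                vals.append(cache[b][within])
            out[f] = vals
        return out

    # -- extension -----------------------------------------------------------

    def add_annotation_channel(self, name: str, kind: str, values: Sequence) -> None:
        """Append an annotation channel and rewrite the file in place.

        Existing channels are copied compressed-bytes-verbatim; the new
        channel is retrievable immediately and after reopening.
        """
        if kind not in ("float64", "text"):
            raise ContainerError(f"channel kind must be float64 or text, got {kind!r}")
        if name in self.header["channels"]:
            raise ContainerError(f"channel {name!r} already exists")
        if len(values) != self.n_variants:
            raise ContainerError(
                f"channel {name!r} has {len(values)} values for "
                f"{self.n_variants} variants"
            )
        with open(self.path, "rb") as fh:
            fh.seek(self._data_start)
            payload = bytearray(fh.read())
        entries = []
        for lo, hi in _blocks_of(self.n_variants, self.block_size):
            raw = _encode_values(kind, values[lo:hi])
            comp = _compress(self.codec, raw)
            entries.append([len(payload), len(comp), len(raw)])
            payload.extend(comp)
        header = self.header
        header["channels"][name] = {
            "kind": kind,
            "n": self.n_variants,
            "blocks": entries,
        }
        header["channel_order"].append(name)
        header["annotation_fields"].append(name)
        _write_file(self.path, header, bytes(payload))
        # refresh offsets
        self.__init__(self.path)

    # -- validation ----------------------------------------------------------

    def validate(self) -> dict[str, dict]:
        """Integrity report: per-check pass/fail with detail.

        Checks channel lengths, every block's decode, genotype index-vector
        consistency with the overflow list, and key sortedness within each
        chromosome.  Corrupt blocks are flagged in the report rather than
        raised.
        """
        report: dict[str, dict] = {}

        lengths_ok, length_detail = True, []
        for name, ch in self.header["channels"].items():
            expect = ch["n"]
            n_blocks = len(ch["blocks"])
            want_blocks = max(1, -(-expect // self.block_size)) if expect else 0
            if n_blocks != want_blocks:
                lengths_ok = False
                length_detail.append(f"{name}: {n_blocks} blocks, expected {want_blocks}")
            if name != "sample_ids" and ch["kind"] != "genotype" and expect != self.n_variants:
                lengths_ok = False
                length_detail.append(f"{name}: length {expect} != {self.n_variants}")
        report["channel_lengths"] = {
            "pass": lengths_ok,
            "detail": "; ".join(length_detail) or "all channels variant-aligned",
        }

        bad_blocks = []
        for name, ch in self.header["channels"].items():
            for b in range(len(ch["blocks"])):
                try:
                    self._read_block(name, b)
                except Exception as exc:  # corrupt data must not abort validation
                    bad_blocks.append(f"{name}[{b}]: {exc}")
        report["block_decode"] = {
            "pass": not bad_blocks,
            "detail": "; ".join(bad_blocks) or "every block decodes",
        }

        if self.has_genotypes:
            ok = True
            detail = "index vector matches overflow list"
            try:
                idx = np.asarray(self._read_channel_blocks("genotype_index"))
                over_variants = {v for v, _, _, _ in self.header["overflow"]}
                expect = np.zeros(self.n_variants, dtype=np.uint8)
                for v in over_variants:
                    expect[v] = 1
                if not np.array_equal(idx, expect):
                    ok = False
                    detail = "index vector inconsistent with overflow list"
            except Exception as exc:
                ok, detail = False, str(exc)
            report["genotype_index"] = {"pass": ok, "detail": detail}
        else:
            report["genotype_index"] = {
                "pass": True,
                "detail": "sites-only container: genotype checks skipped",
            }

        try:
            chroms = self._read_channel_blocks("variant_chrom")
            pos = self._read_channel_blocks("variant_pos")
            sorted_ok = all(
                not (chroms[i] == chroms[i - 1] and pos[i] < pos[i - 1])
                for i in range(1, len(chroms))
            )
            report["key_sorted_within_chrom"] = {
                "pass": bool(sorted_ok),
                "detail": "positions non-decreasing within each chromosome run"
                if sorted_ok
                else "position order violation within a chromosome",
            }
        except Exception as exc:
            report["key_sorted_within_chrom"] = {"pass": False, "detail": str(exc)}
        return report
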