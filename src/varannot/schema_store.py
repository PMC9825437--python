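"""Schema registry and the keyed, range-indexed annotation store.

The store joins per-category delimited source tables on the canonical
``chr-pos-ref-alt`` primary key into one record per distinct variant, keeps
SNVs and indels in separate partitions, and serves exact-key, rsID-alias,
region and gene queries.  Results are independent of the backing structures:
a range scan always equals a brute-force linear scan.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from varannot.registry_config import default_registry_config
from varannot.variant_core import (
    VariantClass,
    VariantKey,
    classify_variant,
    parse_variant_token,
    KeyQuery,
)

logger = logging.getLogger(__name__)

KEY_COLUMN = "variant_vcf"
FIELD_KINDS = ("numeric", "categorical", "text", "flag")

#: chromosome sort order used everywhere records are ordered
CHROM_ORDER = {c: i for i, c in enumerate([str(i) for i in range(1, 23)] + ["X", "Y", "M"])}


class RegistryError(ValueError):
    """Invalid registry description (duplicates, unknown category, ...)."""


class StoreBuildError(ValueError):
    """Raised when source tables cannot be joined into a consistent store."""


@dataclass(frozen=True)
class FieldDescriptor:
    """One annotation field: value kind, major category, display block."""

    name: str
    kind: str
    category: str
    block: str
    phred_scaled: bool = False

    @property
    def missing_sentinel(self):
        return np.nan if self.kind == "numeric" else ""


class SchemaRegistry:
    """Ordered catalog of annotation fields.

    Exposes the full field list, the "essential" subset, the single-variant
    block layout, the region-table column list and the aPC component
    groupings.
    """

    def __init__(
        self,
        fields: Sequence[FieldDescriptor],
        categories: Sequence[str],
        blocks: Sequence[str],
        essential: Sequence[str],
        region_columns: Sequence[str],
        apc_components: Mapping[str, Sequence[str]],
    ):
        self.fields = list(fields)
        self.categories = list(categories)
        self.blocks = list(blocks)
        self.essential = list(essential)
        self.region_columns = list(region_columns)
        self.apc_components = {k: list(v) for k, v in apc_components.items()}
        self.by_name = {f.name: f for f in self.fields}
        self.field_names = [f.name for f in self.fields]

    def __len__(self) -> int:
        return len(self.fields)

    def __contains__(self, name: str) -> bool:
        return name in self.by_name

    @property
    def numeric_fields(self) -> list[str]:
        return [f.name for f in self.fields if f.kind == "numeric"]

    @property
    def phred_scaled_fields(self) -> list[str]:
        return [f.name for f in self.fields if f.phred_scaled]

    def block_layout(self) -> dict[str, list[str]]:
        """Display blocks -> ordered member fields (a partition of the fields)."""
        layout: dict[str, list[str]] = {b: [] for b in self.blocks}
        for f in self.fields:
            layout[f.block].append(f.name)
        return layout

    def sentinel_for(self, name: str):
        return self.by_name[name].missing_sentinel

    def fields_in_category(self, category: str) -> list[str]:
        return [f.name for f in self.fields if f.category == category]

    def counts(self) -> dict[str, int]:
        return {
            "fields": len(self.fields),
            "categories": len({f.category for f in self.fields}),
            "blocks": len({f.block for f in self.fields}),
            "essential": len(self.essential),
        }


def load_registry(config: Mapping | str | Path | None = None) -> SchemaRegistry:
    """Build and validate a :class:`SchemaRegistry` from a description document.

    ``config`` may be a dict, a path to a YAML/JSON document, or ``None`` for
    the shipped default schema (160 fields, 12 categories, 17 display blocks,
    20 essential fields, 32 region-table columns).
    """
    if config is None:
        config = default_registry_config()
    elif isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)

    categories = list(config["categories"])
    blocks = list(config["blocks"])
    descriptors: list[FieldDescriptor] = []
    seen: set[str] = set()
    for spec in config["fields"]:
        name = spec["name"]
        if name in seen:
            raise RegistryError(f"duplicate field name {name!r}")
        seen.add(name)
        kind = spec["kind"]
        if kind not in FIELD_KINDS:
            raise RegistryError(f"field {name!r} has unknown kind {kind!r}")
        if spec["category"] not in categories:
            raise RegistryError(
                f"field {name!r} has unknown category {spec['category']!r}"
            )
        if spec["block"] not in blocks:
            raise RegistryError(f"field {name!r} has unknown block {spec['block']!r}")
        descriptors.append(
            FieldDescriptor(
                name=name,
                kind=kind,
                category=spec["category"],
                block=spec["block"],
                phred_scaled=bool(spec.get("phred_scaled", False)),
            )
        )

    essential = list(config.get("essential", []))
    missing_essential = [e for e in essential if e not in seen]
    if missing_essential:
        raise RegistryError(
            f"essential fields absent from full set: {missing_essential}"
        )
    region_columns = list(config.get("region_columns", []))
    missing_region = [c for c in region_columns if c not in seen]
    if missing_region:
        raise RegistryError(f"region columns absent from full set: {missing_region}")

    apc_components = {}
    for grouping, comps in config.get("apc_components", {}).items():
        unknown = [c for c in comps if c not in seen]
        if unknown:
            raise RegistryError(
                f"aPC grouping {grouping!r} lists unknown fields: {unknown}"
            )
        apc_components[grouping] = list(comps)

    registry = SchemaRegistry(
        descriptors, categories, blocks, essential, region_columns, apc_components
    )

    expected = config.get("expected_counts")
    if expected:
        got = registry.counts()
        for what, want in expected.items():
            if got.get(what) != want:
                raise RegistryError(
                    f"registry {what} count is {got.get(what)}, expected {want}"
                )
    logger.info("registry loaded: %s", registry.counts())
    return registry


@dataclass
class AnnotationRecord:
    """One variant's annotation vector, aligned to a registry.

    ``values`` maps every registry field name to a value (missing fields
    carry the field's sentinel); ``provenance`` lists the source-table
    categories that contributed at least one non-missing value.
    """

    key: VariantKey
    values: dict
    registry: SchemaRegistry
    provenance: tuple = dc_field(default_factory=tuple)

    def value_list(self) -> list:
        """Values ordered as in the registry."""
        return [self.values[name] for name in self.registry.field_names]

    def __getitem__(self, name: str):
        return self.values[name]

    def is_missing(self, name: str) -> bool:
        v = self.values[name]
        if self.registry.by_name[name].kind == "numeric":
            return v is None or (isinstance(v, float) and np.isnan(v))
        return v == "" or v is None


def _chrom_rank(chrom: str) -> int:
    return CHROM_ORDER.get(chrom, len(CHROM_ORDER))


class AnnotationStore:
    """Keyed + range-indexed collection of annotation records.

    Records live in two pandas partitions (SNV / indel) indexed by the
    canonical key string; auxiliary indices serve rsID-alias and
    per-chromosome interval lookups.
    """

    def __init__(
        self,
        registry: SchemaRegistry,
        snv: pd.DataFrame,
        indel: pd.DataFrame,
        aliases: pd.DataFrame | None = None,
        provenance: Mapping[str, tuple] | None = None,
    ):
        self.registry = registry
        self.snv = snv
        self.indel = indel
        self.provenance = dict(provenance or {})
        # rsID -> keys (many-to-many); keep only syntactic validity here,
        # presence in the store is checked at query time
        self._rsid_index: dict[str, list[str]] = {}
        if aliases is not None and len(aliases):
            for rsid, key in zip(aliases["rsid"], aliases["key"]):
                self._rsid_index.setdefault(str(rsid), []).append(str(key))
        self._build_interval_index()

    # -- construction helpers -------------------------------------------------

    def _build_interval_index(self) -> None:
        parts = [df for df in (self.snv, self.indel) if len(df)]
        if parts:
            meta = pd.concat(
                [df[["_chrom", "_pos"]] for df in parts], axis=0
            ).reset_index(names="key")
        else:
            meta = pd.DataFrame(columns=["key", "_chrom", "_pos"])
        self._by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
        for chrom, grp in meta.groupby("_chrom", sort=False):
            order = np.argsort(grp["_pos"].to_numpy(), kind="stable")
            pos = grp["_pos"].to_numpy()[order].astype(np.int64)
            keys = grp["key"].to_numpy()[order].tolist()
            self._by_chrom[str(chrom)] = (pos, keys)

    # -- record materialisation ----------------------------------------------

    def _row_to_record(self, key_str: str, row: pd.Series) -> AnnotationRecord:
        values = {name: row[name] for name in self.registry.field_names}
        kq = parse_variant_token(key_str)
        assert isinstance(kq, KeyQuery)
        return AnnotationRecord(
            key=kq.key,
            values=values,
            registry=self.registry,
            provenance=self.provenance.get(key_str, ()),
        )

    def __len__(self) -> int:
        return len(self.snv) + len(self.indel)

    def keys(self) -> list[str]:
        return list(self.snv.index) + list(self.indel.index)

    # -- queries ---------------------------------------------------------------

    def get_by_key(self, key: VariantKey | str) -> AnnotationRecord | None:
        """Exact-match lookup; ``None`` when the key is absent (never fabricated)."""
        key_str = str(key)
        for part in (self.snv, self.indel):
            if key_str in part.index:
                return self._row_to_record(key_str, part.loc[key_str])
        return None

    def get_by_rsid(self, rsid: str) -> list[AnnotationRecord]:
        """All records aliased to ``rsid`` (multi-allelic rsIDs yield several)."""
        records = []
        for key_str in self._rsid_index.get(rsid, []):
            rec = self.get_by_key(key_str)
            if rec is not None:
                records.append(rec)
        return records

    def get_by_point(self, chrom: str, pos: int) -> list[AnnotationRecord]:
        """All records anchored exactly at (chrom, pos)."""
        return self.get_by_range(chrom, pos, pos)

    def get_by_range(self, chrom: str, start: int, end: int) -> list[AnnotationRecord]:
        """Records with ``start <= pos <= end`` on ``chrom``, sorted by
        (chrom, pos, ref, alt)."""
        if start > end:
            raise ValueError(f"range start {start} exceeds end {end}")
        entry = self._by_chrom.get(str(chrom))
        if entry is None:
            return []
        pos, keys = entry
        lo = int(np.searchsorted(pos, start, side="left"))
        hi = int(np.searchsorted(pos, end, side="right"))
        hit_keys = sorted(
            keys[lo:hi], key=lambda k: _sort_tuple(k)
        )
        return [self.get_by_key(k) for k in hit_keys]

    def get_by_gene(self, symbol: str, gene_model: "GeneModel") -> list[AnnotationRecord]:
        """Records inside the gene footprint (min start to max end over all
        the gene's transcripts)."""
        chrom, start, end = gene_model.footprint(symbol)
        return self.get_by_range(chrom, start, end)

    # -- mutation (used by the aPC computation) --------------------------------

    def set_snv_column(self, field: str, values: np.ndarray | float | str) -> None:
        if field not in self.registry.by_name:
            raise KeyError(f"unknown registry field {field!r}")
        self.snv[field] = values


def _sort_tuple(key_str: str):
    chrom, pos, ref, alt = key_str.split("-")
    return (_chrom_rank(chrom), int(pos), ref, alt)


def _read_table(path_or_df) -> pd.DataFrame:
    if isinstance(path_or_df, pd.DataFrame):
        return path_or_df.copy()
    p = Path(path_or_df)
    sep = "\t" if p.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(p, sep=sep, dtype={KEY_COLUMN: str})


def build_store(
    source_tables: Iterable[tuple[str, "pd.DataFrame | str | Path"]],
    registry: SchemaRegistry,
    aliases: "pd.DataFrame | str | Path | None" = None,
) -> AnnotationStore:
    """Outer-join per-category source tables into an :class:`AnnotationStore`.

    ``source_tables`` is an iterable of ``(category, table)`` where each table
    (DataFrame or CSV/TSV path) carries a ``variant_vcf`` key column plus
    registry-declared annotation columns.  Every key seen in any table yields
    exactly one record; fields never assigned keep their sentinel.  Two
    different non-missing values for the same (key, field) abort the build
    with an error listing the collisions.
    """
    long_frames = []
    provenance_frames = []
    for category, table in source_tables:
        df = _read_table(table)
        if KEY_COLUMN not in df.columns:
            raise StoreBuildError(
                f"source table for category {category!r} lacks the "
                f"{KEY_COLUMN!r} key column"
            )
        value_cols = [c for c in df.columns if c != KEY_COLUMN]
        unknown = [c for c in value_cols if c not in registry.by_name]
        if unknown:
            raise StoreBuildError(
                f"source table for category {category!r} declares columns "
                f"absent from the registry: {unknown}"
            )
        melted = df.melt(id_vars=[KEY_COLUMN], var_name="field", value_name="value")
        melted = melted.dropna(subset=["value"])
        # empty strings are the non-numeric missing sentinel
        melted = melted[melted["value"].astype(str) != ""]
        long_frames.append(melted)
        provenance_frames.append(
            pd.DataFrame({KEY_COLUMN: df[KEY_COLUMN].unique(), "category": category})
        )

    if long_frames:
        long = pd.concat(long_frames, ignore_index=True)
    else:
        long = pd.DataFrame(columns=[KEY_COLUMN, "field", "value"])

    # collision check: same (key, field) with two distinct non-missing values
    if len(long):
        nun = long.groupby([KEY_COLUMN, "field"])["value"].nunique()
        collisions = nun[nun > 1]
        if len(collisions):
            listing = ", ".join(f"{k}/{f}" for k, f in collisions.index[:20])
            raise StoreBuildError(
                f"{len(collisions)} conflicting (key, field) assignment(s): {listing}"
            )
        wide = long.pivot_table(
            index=KEY_COLUMN, columns="field", values="value", aggfunc="first"
        )
    else:
        wide = pd.DataFrame()

    all_keys = sorted(set(long[KEY_COLUMN]) if len(long) else set(), key=_sort_tuple)
    wide = wide.reindex(index=all_keys, columns=registry.field_names)

    # enforce per-field dtype and sentinel
    for f in registry.fields:
        if f.kind == "numeric":
            wide[f.name] = pd.to_numeric(wide[f.name], errors="raise")
        else:
            wide[f.name] = wide[f.name].fillna("").astype(str)

    parts = pd.DataFrame(
        [k.split("-") for k in all_keys],
        index=all_keys,
        columns=["_chrom", "_pos", "_ref", "_alt"],
    )
    if len(parts):
        parts["_pos"] = parts["_pos"].astype(np.int64)
    wide = pd.concat([parts, wide], axis=1)

    is_snv = np.array(
        [
            classify_variant(parse_variant_token(k).key) is VariantClass.SNV
            for k in all_keys
        ],
        dtype=bool,
    )
    snv = wide.loc[np.asarray(all_keys, dtype=object)[is_snv]]
    indel = wide.loc[np.asarray(all_keys, dtype=object)[~is_snv]]

    provenance: dict[str, tuple] = {}
    for pf in provenance_frames:
        for k in pf[KEY_COLUMN]:
            provenance.setdefault(str(k), ())
            provenance[str(k)] = provenance[str(k)] + (pf["category"].iloc[0],)

    alias_df = None
    if aliases is not None:
        alias_df = (
            aliases.copy()
            if isinstance(aliases, pd.DataFrame)
            else pd.read_csv(aliases, sep="\t", dtype=str)
        )
        if not {"rsid", "key"}.issubset(alias_df.columns):
            raise StoreBuildError("alias table must have 'rsid' and 'key' columns")

    logger.info(
        "store built: %d SNV records, %d indel records", len(snv), len(indel)
    )
    return AnnotationStore(registry, snv, indel, alias_df, provenance)


class GeneModel:
    """Gene symbol -> genomic footprint, backed by a GTF/GFF3 gene model."""

    def __init__(self, footprints: Mapping[str, tuple[str, int, int]]):
        self._footprints = dict(footprints)

    @classmethod
    def from_gtf(cls, path: str | Path) -> "GeneModel":
        """Parse a GTF/GFF3 file with :mod:`gffutils` and record, per gene
        symbol, the span from the minimum start to the maximum end across all
        the gene's transcripts."""
        import gffutils

        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="merge",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        spans: dict[str, tuple[str, int, int]] = {}
        for feat in db.all_features():
            names = feat.attributes.get("gene_name") or feat.attributes.get("gene_id")
            if not names:
                continue
            symbol = names[0]
            chrom = feat.seqid
            if chrom.lower().startswith("chr"):
                chrom = chrom[3:]
            start, end = int(feat.start), int(feat.end)
            if symbol in spans:
                c, s, e = spans[symbol]
                spans[symbol] = (c, min(s, start), max(e, end))
            else:
                spans[symbol] = (chrom, start, end)
        return cls(spans)

    def symbols(self) -> list[str]:
        return sorted(self._footprints)

    def footprint(self, symbol: str) -> tuple[str, int, int]:
        """(chrom, start, end) of the gene body; unknown symbols raise a
        KeyError listing near-matches."""
        try:
            return self._footprints[symbol]
        except KeyError:
            near = difflib.get_close_matches(symbol, self._footprints, n=3)
            raise KeyError(
                f"unknown gene symbol {symbol!r}"
                + (f"; close matches: {near}" if near else "")
            ) from None
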