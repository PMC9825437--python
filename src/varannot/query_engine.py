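"""Query surface: single-variant, region/gene and batch queries over an
annotation store, producing block-organised reports exportable to CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from varannot.schema_store import AnnotationRecord, AnnotationStore, GeneModel
from varannot.summary_engine import (
    RegionSummary,
    flag_variant,
    keyword_filter,
    region_table,
    select_display,
    summarize_region,
)
from varannot.variant_core import (
    KeyQuery,
    PointQuery,
    RsidQuery,
    VariantParseError,
    parse_variant_token,
    split_multiallelic,
)

DEFAULT_BATCH_LIMIT = 10_000
FIGURE_BINS = 50


class BatchLimitError(ValueError):
    """Batch file exceeds the configured variant limit."""


@dataclass
class SingleVariantReport:
    """Single-variant result: summary flags, block layout, figure data."""

    key: str
    flags: list
    blocks: dict[str, pd.DataFrame]
    figures: dict[str, dict]

    @property
    def found(self) -> bool:
        return True


@dataclass
class NotFound:
    query: str

    @property
    def found(self) -> bool:
        return False


@dataclass
class RegionReport:
    summary: RegionSummary
    table: pd.DataFrame
    records: list = dc_field(default_factory=list, repr=False)

    def filtered(self, text: str) -> pd.DataFrame:
        return region_table(keyword_filter(self.records, text))


@dataclass
class BatchResult:
    """Per-row annotation output; order equals input order."""

    table: pd.DataFrame
    row_errors: list


def _figure_data(store: AnnotationStore, record: AnnotationRecord) -> dict[str, dict]:
    """Store-wide histogram + the variant's marker, per PHRED-scaled field."""
    figures = {}
    registry = store.registry
    pool = pd.concat([store.snv, store.indel]) if len(store.indel) else store.snv
    for f in registry.phred_scaled_fields:
        values = pd.to_numeric(pool[f], errors="coerce").dropna().to_numpy()
        if len(values) == 0:
            continue
        lo, hi = float(values.min()), float(values.max())
        if lo == hi:
            hi = lo + 1.0
        counts, edges = np.histogram(values, bins=FIGURE_BINS, range=(lo, hi))
        marker = None if record.is_missing(f) else float(record[f])
        figures[f] = {
            "bin_edges": edges.tolist(),
            "counts": counts.tolist(),
            "variant_value": marker,
        }
    return figures


def query_single(store: AnnotationStore, token) -> "list[SingleVariantReport] | NotFound":
    """Resolve a key/point/rsID token to per-allele reports.

    Each report carries (a) the summary flags, (b) the 17-block full table,
    (c) per PHRED-scaled field the store-wide histogram with the variant's
    value marked.  An unmatched query returns :class:`NotFound`, not an
    error.
    """
    if isinstance(token, str):
        token = parse_variant_token(token)
    if isinstance(token, KeyQuery):
        rec = store.get_by_key(token.key)
        records = [rec] if rec is not None else []
        label = str(token.key)
    elif isinstance(token, PointQuery):
        records = store.get_by_point(token.chrom, token.pos)
        label = f"{token.chrom}-{token.pos}"
    elif isinstance(token, RsidQuery):
        records = store.get_by_rsid(token.rsid)
        label = token.rsid
    else:
        raise TypeError(f"unsupported query token {token!r}")
    if not records:
        return NotFound(label)
    return [
        SingleVariantReport(
            key=str(rec.key),
            flags=flag_variant(rec),
            blocks=select_display(rec, "single_blocks"),
            figures=_figure_data(store, rec),
        )
        for rec in records
    ]


def _region_report(records: Sequence[AnnotationRecord]) -> RegionReport:
    return RegionReport(
        summary=summarize_region(records),
        table=region_table(records),
        records=list(records),
    )


def query_region(store: AnnotationStore, chrom: str, start: int, end: int) -> RegionReport:
    """Summary + 32-column table for all variants in [start, end] on chrom."""
    return _region_report(store.get_by_range(chrom, start, end))


def query_gene(store: AnnotationStore, symbol: str, gene_model: GeneModel) -> RegionReport:
    """Region query over the gene's footprint (all transcripts spanned)."""
    return _region_report(store.get_by_gene(symbol, gene_model))


def _batch_tokens(path: Path, fmt: str) -> list[str]:
    tokens = []
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                tokens.append(line.split(sep)[0].strip())
    elif fmt == "vcf":
        import pysam

        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                for key in split_multiallelic(rec):
                    tokens.append(str(key))
    else:
        raise ValueError(
            f"unsupported batch format {fmt!r}; core formats are csv, tsv, vcf "
            "(spreadsheet/serialized-object adapters plug in separately)"
        )
    return tokens


def batch_annotate(
    path: str | Path,
    fmt: str,
    store: AnnotationStore,
    limit: int = DEFAULT_BATCH_LIMIT,
) -> BatchResult:
    """Annotate a batch file of variant tokens.

    The row count is checked against ``limit`` (default 10,000) BEFORE any
    annotation work; oversized files are rejected outright.  Each input row
    yields one output row group in input order — point/rsID rows expand to
    every matching allele, unresolvable rows yield an error entry rather
    than a silent omission.  The output table carries the input row number,
    the token, the resolved key, and all registry annotation columns.
    """
    path = Path(path)
    tokens = _batch_tokens(path, fmt)
    if not tokens:
        raise ValueError(f"batch file {path} contains no variant rows")
    if len(tokens) > limit:
        raise BatchLimitError(
            f"batch file has {len(tokens)} variants, exceeding the limit of {limit}"
        )

    registry = store.registry
    rows = []
    errors = []
    for row_no, token in enumerate(tokens, start=1):
        try:
            q = parse_variant_token(token)
        except VariantParseError as exc:
            errors.append({"row": row_no, "token": token, "error": str(exc)})
            continue
        if isinstance(q, KeyQuery):
            rec = store.get_by_key(q.key)
            records = [rec] if rec is not None else []
        elif isinstance(q, PointQuery):
            records = store.get_by_point(q.chrom, q.pos)
        elif isinstance(q, RsidQuery):
            records = store.get_by_rsid(q.rsid)
        else:
            records = []
        if not records:
            errors.append(
                {"row": row_no, "token": token, "error": "no matching variant"}
            )
            continue
        for rec in records:
            row = {"row": row_no, "token": token, "variant_vcf": str(rec.key)}
            row.update({f: rec.values[f] for f in registry.field_names})
            rows.append(row)
    table = pd.DataFrame(
        rows, columns=["row", "token", "variant_vcf"] + registry.field_names
    )
    return BatchResult(table=table, row_errors=errors)


def export_results(report, path: str | Path) -> Path:
    """Serialise any report type to CSV ("download query results").

    Region reports export the per-variant table; batch results the row
    table; single-variant reports a long (block, field, value) table.
    Parsed CSV content round-trips to the displayed values.
    """
    path = Path(path)
    if isinstance(report, RegionReport):
        report.table.to_csv(path, index=False)
    elif isinstance(report, BatchResult):
        report.table.to_csv(path, index=False)
    elif isinstance(report, SingleVariantReport):
        rows = []
        for block, tab in report.blocks.items():
            for _, r in tab.iterrows():
                rows.append({"block": block, "field": r["field"], "value": r["value"]})
        pd.DataFrame(rows, columns=["block", "field", "value"]).to_csv(path, index=False)
    elif isinstance(report, list) and report and isinstance(report[0], SingleVariantReport):
        frames = []
        for rep in report:
            for block, tab in rep.blocks.items():
                for _, r in tab.iterrows():
                    frames.append(
                        {"variant_vcf": rep.key, "block": block, "field": r["field"], "value": r["value"]}
                    )
        pd.DataFrame(frames).to_csv(path, index=False)
    elif isinstance(report, NotFound):
        pd.DataFrame(columns=["query", "found"]).to_csv(path, index=False)
    else:
        raise TypeError(f"cannot export report of type {type(report).__name__}")
    return path
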