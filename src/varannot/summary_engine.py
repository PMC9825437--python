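"""Interpretation layer: functional flags, region summaries, keyword
filtering and display layouts.

The flagging defaults mirror the conventional "plausibly functional"
evidence rules: a damaging protein-impact prediction (PolyPhen score 1,
probably damaging; SIFT score 0, deleterious), a ClinVar significance
containing "pathogenic", or any PHRED-scaled integrative score above 10
(top 10% of the ranking population).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from varannot.schema_store import AnnotationRecord, SchemaRegistry

#: fixed allele-frequency histogram bin edges (log-spaced; recorded in output)
AF_BIN_EDGES = [0.0, 1e-4, 1e-3, 1e-2, 1e-1, 0.5, 1.0]
AF_BIN_LABELS = [
    "[0,1e-4)",
    "[1e-4,1e-3)",
    "[1e-3,1e-2)",
    "[1e-2,1e-1)",
    "[1e-1,0.5)",
    "[0.5,1]",
]

#: AF sources tried in order when binning a record (first non-missing wins)
AF_SOURCE_FIELDS = ("af_topmed", "af_gnomad", "af_1000g")

PHRED_FLAG_THRESHOLD = 10.0


@dataclass(frozen=True)
class FlagRule:
    """One evidence rule: field + predicate + human-readable label."""

    field: str
    label: str
    predicate: Callable[[object], bool]


def default_flag_rules(registry: SchemaRegistry) -> list[FlagRule]:
    """The portal's default evidence rules against this registry."""
    rules = [
        FlagRule(
            "polyphen2_hdiv_score",
            "PolyPhen probably_damaging (score 1)",
            lambda v: float(v) == 1.0,
        ),
        FlagRule(
            "sift_score",
            "SIFT deleterious (score 0)",
            lambda v: float(v) == 0.0,
        ),
        FlagRule(
            "clinvar_significance",
            "ClinVar significance contains Pathogenic",
            lambda v: "pathogenic" in str(v).lower(),
        ),
    ]
    for name in registry.phred_scaled_fields:
        rules.append(
            FlagRule(
                name,
                f"{name} > {PHRED_FLAG_THRESHOLD:g} on the PHRED scale (top 10%)",
                lambda v: float(v) > PHRED_FLAG_THRESHOLD,
            )
        )
    return rules


def flag_variant(
    record: AnnotationRecord, rules: Sequence[FlagRule] | None = None
) -> list[tuple[str, str, object]]:
    """Evaluate the evidence rules on one record.

    Returns ``(label, field, value)`` triples for every rule that fires on a
    non-missing value; an empty list when nothing fires.  A rule referencing
    a field absent from the registry is a configuration error.
    """
    registry = record.registry
    if rules is None:
        rules = default_flag_rules(registry)
    flags = []
    for rule in rules:
        if rule.field not in registry.by_name:
            raise KeyError(f"flag rule references unknown field {rule.field!r}")
        if record.is_missing(rule.field):
            continue
        if rule.predicate(record[rule.field]):
            flags.append((rule.label, rule.field, record[rule.field]))
    return flags


@dataclass
class RegionSummary:
    """Summary statistics of the variants in one region or gene."""

    total: int
    af_histogram: dict[str, int]
    af_bin_edges: list[float]
    af_source_fields: tuple[str, ...]
    gencode_counts: dict[str, int]
    clinvar_counts: dict[str, int]
    consequence_counts: dict[str, int]
    high_integrative_count: int

    def as_tables(self) -> dict[str, pd.DataFrame]:
        def tab(d):
            return pd.DataFrame({"value": list(d.keys()), "count": list(d.values())})

        return {
            "allele_frequency_distribution": tab(self.af_histogram),
            "gencode_category": tab(self.gencode_counts),
            "clinvar_clinical_significance": tab(self.clinvar_counts),
            "functional_consequences": tab(self.consequence_counts),
            "high_integrative_scores": pd.DataFrame(
                {"value": [f"PHRED > {PHRED_FLAG_THRESHOLD:g}"], "count": [self.high_integrative_count]}
            ),
        }


def _record_af(record: AnnotationRecord) -> float | None:
    for f in AF_SOURCE_FIELDS:
        if f in record.registry.by_name and not record.is_missing(f):
            return float(record[f])
    return None


def summarize_region(records: Sequence[AnnotationRecord]) -> RegionSummary:
    """Tally a record list into a :class:`RegionSummary`.

    Missing values are uncounted, so each count table sums to at most the
    total.  The AF histogram uses the fixed log-spaced bins recorded in the
    output; the AF per record is the first non-missing of
    ``af_topmed, af_gnomad, af_1000g``.  The high-integrative count is the
    number of variants with *any* PHRED-scaled field above 10.
    """
    af_hist = {label: 0 for label in AF_BIN_LABELS}
    gencode: dict[str, int] = {}
    clinvar: dict[str, int] = {}
    consequence: dict[str, int] = {}
    high = 0
    for rec in records:
        af = _record_af(rec)
        if af is not None:
            idx = int(np.searchsorted(AF_BIN_EDGES, af, side="right")) - 1
            idx = min(idx, len(AF_BIN_LABELS) - 1)
            af_hist[AF_BIN_LABELS[idx]] += 1
        if not rec.is_missing("gencode_category"):
            gencode[rec["gencode_category"]] = gencode.get(rec["gencode_category"], 0) + 1
        if not rec.is_missing("clinvar_significance"):
            v = rec["clinvar_significance"]
            clinvar[v] = clinvar.get(v, 0) + 1
        if not rec.is_missing("gencode_exonic_category"):
            v = rec["gencode_exonic_category"]
            consequence[v] = consequence.get(v, 0) + 1
        if any(
            not rec.is_missing(f) and float(rec[f]) > PHRED_FLAG_THRESHOLD
            for f in rec.registry.phred_scaled_fields
        ):
            high += 1
    return RegionSummary(
        total=len(records),
        af_histogram=af_hist,
        af_bin_edges=list(AF_BIN_EDGES),
        af_source_fields=AF_SOURCE_FIELDS,
        gencode_counts=gencode,
        clinvar_counts=clinvar,
        consequence_counts=consequence,
        high_integrative_count=high,
    )


def _render_value(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return "" if np.isnan(v) else f"{v:.6g}"
    return str(v)


def region_table(records: Sequence[AnnotationRecord]) -> pd.DataFrame:
    """The region/gene per-variant display table: key + the registry's
    32 commonly used annotation columns; sortable by any column."""
    if not records:
        cols = ["variant_vcf"]
        return pd.DataFrame(columns=cols)
    registry = records[0].registry
    rows = []
    for rec in records:
        row = {"variant_vcf": str(rec.key)}
        for c in registry.region_columns:
            row[c] = rec.values[c]
        rows.append(row)
    return pd.DataFrame(rows)


def keyword_filter(
    records: Sequence[AnnotationRecord], text: str
) -> list[AnnotationRecord]:
    """Case-insensitive substring filter over the rendered region-table
    values of each record; empty text keeps everything."""
    if text == "":
        return list(records)
    needle = text.lower()
    kept = []
    for rec in records:
        rendered = [str(rec.key)] + [
            _render_value(rec.values[c]) for c in rec.registry.region_columns
        ]
        if any(needle in r.lower() for r in rendered):
            kept.append(rec)
    return kept


def select_display(
    record_or_records, mode: str
) -> "dict[str, pd.DataFrame] | pd.DataFrame":
    """Lay out records for display.

    ``single_blocks``: one record -> 17 named blocks, each a (field, value)
    table; together the blocks partition the displayed fields.
    ``region_table``: record list -> the 32-column per-variant table.
    """
    if mode == "single_blocks":
        rec: AnnotationRecord = record_or_records
        layout = rec.registry.block_layout()
        return {
            block: pd.DataFrame(
                {
                    "field": fields,
                    "value": [_render_value(rec.values[f]) for f in fields],
                }
            )
            for block, fields in layout.items()
        }
    if mode == "region_table":
        return region_table(list(record_or_records))
    raise ValueError(f"unknown display mode {mode!r}")


def sort_region_table(table: pd.DataFrame, by: str, ascending: bool = True) -> pd.DataFrame:
    """Stable sort of the region table by any column."""
    return table.sort_values(by=by, ascending=ascending, kind="stable").reset_index(
        drop=True
    )
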