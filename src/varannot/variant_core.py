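"""Variant identity: parsing, formatting, classification.

Every other module keys data by the canonical ``chr-pos-ref-alt`` string
(e.g. ``19-44908822-C-T``): chromosome without a ``chr`` prefix, 1-based
position of the first reference base, then the reference and alternate
alleles in their VCF-anchored representation.  Indels are deliberately NOT
re-trimmed or left-normalised beyond what the VCF states — exact string
equality against source-table keys is the join mechanism, so the key must
match the source verbatim (``1-10253-CTA-C`` stays ``1-10253-CTA-C``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from typing import Union

logger = logging.getLogger(__name__)

_VALID_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X", "Y", "M"])
_ALLELE_RE = re.compile(r"^[ACGT]+$")
_RSID_RE = re.compile(r"^rs\d+$")


class VariantClass(str, Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"
    MNV = "MNV"


class VariantParseError(ValueError):
    """Raised when a token or allele cannot be interpreted as a variant."""


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr``/``CHR`` prefix and validate the label.

    Accepts 1-22, X, Y and M (MT is normalised to M).
    """
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    c = c.upper() if not c.isdigit() else c
    if c == "MT":
        c = "M"
    if c not in _VALID_CHROMS:
        raise VariantParseError(f"invalid chromosome label: {chrom!r}")
    return c


@dataclass(frozen=True, order=True)
class VariantKey:
    """Canonical identity of a variant: (chrom, pos, ref, alt).

    ``pos`` is the 1-based position of the first reference base.  Alleles
    are uppercase ACGT strings in VCF-anchored form.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if self.pos < 1:
            raise VariantParseError(f"position must be >= 1, got {self.pos}")
        for label, allele in (("ref", self.ref), ("alt", self.alt)):
            if not _ALLELE_RE.match(allele):
                raise VariantParseError(
                    f"{label} allele must be a non-empty ACGT string, got {allele!r}"
                )
        if self.ref == self.alt:
            raise VariantParseError(
                f"ref and alt alleles are identical ({self.ref!r})"
            )

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def __str__(self) -> str:
        return f"{self.chrom}-{self.pos}-{self.ref}-{self.alt}"


@dataclass(frozen=True)
class KeyQuery:
    key: VariantKey


@dataclass(frozen=True)
class PointQuery:
    chrom: str
    pos: int


@dataclass(frozen=True)
class RsidQuery:
    rsid: str


@dataclass(frozen=True)
class RegionQuery:
    """1-based closed interval [start, end] on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"region start {self.start} exceeds end {self.end}"
            )


@dataclass(frozen=True)
class GeneQuery:
    symbol: str


QueryToken = Union[KeyQuery, PointQuery, RsidQuery, RegionQuery, GeneQuery]


def format_key(key: VariantKey) -> str:
    """Render a key in its canonical dash-joined form, e.g. ``19-44908822-C-T``."""
    return str(key)


def parse_variant_token(text: str) -> QueryToken:
    """Parse one free-text variant token into a query.

    Supported forms:

    * ``chrom-pos-ref-alt`` -> :class:`KeyQuery` (e.g. ``1-10253-CTA-C``)
    * ``chrom-pos``          -> :class:`PointQuery` (e.g. ``1-10253``)
    * ``rs<digits>``         -> :class:`RsidQuery` (e.g. ``rs868413313``)

    A leading ``chr`` on the chromosome is stripped.  Malformed tokens raise
    :class:`VariantParseError` naming the offending component.
    """
    token = text.strip()
    if not token:
        raise VariantParseError("empty variant token")
    if _RSID_RE.match(token):
        return RsidQuery(token)
    if token.lower().startswith("rs"):
        raise VariantParseError(
            f"malformed rsID {token!r}: expected 'rs' followed by digits"
        )
    parts = token.split("-")
    if len(parts) not in (2, 4):
        raise VariantParseError(
            f"token {token!r} has {len(parts)} dash-separated parts; "
            "expected 2 (chrom-pos) or 4 (chrom-pos-ref-alt)"
        )
    chrom = normalize_chrom(parts[0])
    if not parts[1].isdigit():
        raise VariantParseError(
            f"position component {parts[1]!r} of {token!r} is not a positive integer"
        )
    pos = int(parts[1])
    if pos < 1:
        raise VariantParseError(f"position must be >= 1, got {pos}")
    if len(parts) == 2:
        return PointQuery(chrom, pos)
    ref, alt = parts[2].upper(), parts[3].upper()
    for label, allele in (("ref", ref), ("alt", alt)):
        if not _ALLELE_RE.match(allele):
            raise VariantParseError(
                f"{label} allele component {allele!r} of {token!r} is not an ACGT string"
            )
    return KeyQuery(VariantKey(chrom, pos, ref, alt))


def classify_variant(key: VariantKey) -> VariantClass:
    """Classify a key as SNV, insertion, deletion or MNV.

    SNV: both alleles length 1.  Insertion: alt longer than ref.  Deletion:
    ref longer than alt.  MNV: equal lengths > 1.
    """
    if key.is_snv:
        return VariantClass.SNV
    if len(key.alt) > len(key.ref):
        return VariantClass.INSERTION
    if len(key.ref) > len(key.alt):
        return VariantClass.DELETION
    return VariantClass.MNV


def split_multiallelic(site) -> list[VariantKey]:
    """One :class:`VariantKey` per alternate allele of a parsed VCF site.

    ``site`` is any object exposing ``chrom``/``pos``/``ref``/``alts``
    (a :class:`pysam.VariantRecord` qualifies).  Alleles are kept in the
    VCF's left-anchored representation; order follows ALT order.  Symbolic
    alleles (``<DEL>``, breakends) and ``*`` spanning-deletion alleles are
    skipped with a logged warning.
    """
    keys: list[VariantKey] = []
    alts = site.alts or ()
    for alt in alts:
        if alt is None or alt == "*" or not _ALLELE_RE.match(alt.upper()):
            logger.warning(
                "skipping non-sequence ALT allele %r at %s:%s", alt, site.chrom, site.pos
            )
            continue
        keys.append(VariantKey(str(site.chrom), int(site.pos), site.ref, alt))
    return keys
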