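"""Filter VCF records against regulatory regions.

Records are matched on the span occupied by the REF allele — the 0-based
half-open interval ``[POS-1, POS-1+len(REF))`` — so a deletion or MNV that
merely straddles a region boundary is kept even when POS itself falls
outside.  Kept lines and the header pass through byte-for-byte unchanged:
no re-normalization, no reordering.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .intervals import AnnotatedInterval, GenomeInterval, normalize_chrom

logger = logging.getLogger(__name__)

__all__ = ["VariantRecord", "VcfParseError", "FilterCounts", "filter_vcf", "annotate_hits", "read_vcf_records"]


class VcfParseError(ValueError):
    """Malformed VCF record; message carries the line number."""


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    raw_line: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF POS must be >= 1, got {self.pos}")
        if not self.ref:
            raise ValueError("REF allele must be non-empty")

    def ref_span(self, build: str) -> GenomeInterval:
        """0-based half-open span occupied by the REF allele."""
        return GenomeInterval(
            normalize_chrom(self.chrom), self.pos - 1, self.pos - 1 + len(self.ref), build
        )

    @property
    def is_symbolic(self) -> bool:
        return "<" in self.alt or "[" in self.alt or "]" in self.alt


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _parse_record(line: str, lineno: int) -> VariantRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 5:
        raise VcfParseError(f"line {lineno}: fewer than 5 VCF columns")
    try:
        pos = int(fields[1])
    except ValueError as exc:
        raise VcfParseError(f"line {lineno}: unparseable POS {fields[1]!r}") from exc
    return VariantRecord(
        chrom=fields[0], pos=pos, ref=fields[3], alt=fields[4], raw_line=line
    )


def read_vcf_records(path: str | Path) -> tuple[list[str], list[VariantRecord]]:
    """Return (header lines, records) of a plain or gzip/bgzip VCF."""
    header: list[str] = []
    records: list[VariantRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                header.append(line)
            elif line.strip():
                records.append(_parse_record(line, lineno))
    return header, records


def _region_trees(
    regions: Sequence[GenomeInterval | AnnotatedInterval], build: str
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        iv = r.interval if isinstance(r, AnnotatedInterval) else r
        if iv.build != build:
            raise ValueError(
                f"region build {iv.build} does not match declared VCF build {build}"
            )
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, r)
    return trees


def _record_overlaps(rec: VariantRecord, trees: dict[str, IntervalTree], build: str) -> list:
    """Interval-tree hits for a record's REF span (or POS base if symbolic)."""
    if rec.is_symbolic:
        span = GenomeInterval(normalize_chrom(rec.chrom), rec.pos - 1, rec.pos, build)
        logger.warning(
            "symbolic allele at %s:%d matched on POS only (END-tag handling not applied)",
            rec.chrom,
            rec.pos,
        )
    else:
        span = rec.ref_span(build)
    tree = trees.get(span.chrom)
    if tree is None:
        return []
    return sorted(tree.overlap(span.start, span.end))


@dataclass(frozen=True)
class FilterCounts:
    kept: int
    dropped: int

    @property
    def total(self) -> int:
        return self.kept + self.dropped


def filter_vcf(
    vcf_path: str | Path,
    regions: Sequence[GenomeInterval | AnnotatedInterval],
    out_path: str | Path,
    build: str,
) -> FilterCounts:
    """Write the subset of records whose REF span overlaps >= 1 region.

    The header is copied verbatim; kept records are byte-identical to the
    input and keep their original order.  The genome build is declared
    explicitly by the caller — it cannot be inferred from a VCF — and must
    match the regions' build.
    """
    if build is None:
        raise ValueError("genome build must be declared explicitly")
    trees = _region_trees(regions, build)
    header, records = read_vcf_records(vcf_path)
    kept = 0
    with open(out_path, "wt", encoding="utf-8", newline="") as out:
        for line in header:
            out.write(line)
        for rec in records:
            if _record_overlaps(rec, trees, build):
                line = rec.raw_line
                out.write(line if line.endswith("\n") else line + "\n")
                kept += 1
    return FilterCounts(kept=kept, dropped=len(records) - kept)


def annotate_hits(
    vcf_path: str | Path,
    regions: Sequence[AnnotatedInterval],
    build: str,
) -> pd.DataFrame:
    """Table with one row per (variant, overlapping region) pair.

    Columns: chrom, pos, ref, alt, region_chrom, region_start, region_end,
    provenance (``dataset|tissue`` tokens joined by ';').
    """
    trees = _region_trees(regions, build)
    _, records = read_vcf_records(vcf_path)
    rows = []
    for rec in records:
        for hit in _record_overlaps(rec, trees, build):
            region = hit.data
            prov = region.provenance_string() if isinstance(region, AnnotatedInterval) else ""
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alt,
                    "region_chrom": region.chrom,
                    "region_start": region.start,
                    "region_end": region.end,
                    "provenance": prov,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "region_chrom",
            "region_start",
            "region_end",
            "provenance",
        ],
    )
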