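"""Interval arithmetic and BED I/O.

All genomic coordinates in this package are BED-style: 0-based, half-open
``[start, end)``.  Conversions from 1-based conventions (VCF positions,
browser display strings) happen only at the respective I/O boundaries.
Every interval carries an explicit genome-build tag (``hg19``/``hg38``);
operations mixing builds raise rather than silently returning nonsense.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

SUPPORTED_BUILDS = ("hg19", "hg38")

__all__ = [
    "GenomeInterval",
    "AnnotatedInterval",
    "BuildMismatchError",
    "BedParseError",
    "overlaps",
    "merge_collapse",
    "intersection_span",
    "total_span",
    "read_bed",
    "write_bed",
    "normalize_chrom",
]


class BuildMismatchError(ValueError):
    """Raised when an operation receives intervals from different genome builds."""


class BedParseError(ValueError):
    """Raised for malformed BED records; the message carries the line number."""


def normalize_chrom(name: str) -> str:
    """Map bare chromosome names onto the UCSC dialect ("1" -> "chr1").

    Mitochondrial "MT" becomes "chrM".  Names already starting with "chr"
    pass through unchanged, as do scaffold-style names.
    """
    if name.startswith("chr"):
        return name
    if name == "MT":
        return "chrM"
    return "chr" + name


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A build-tagged genomic span, 0-based half-open."""

    chrom: str
    start: int
    end: int
    build: str = "hg38"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "need 0 <= start < end"
            )
        if self.build not in SUPPORTED_BUILDS:
            raise ValueError(f"unsupported build {self.build!r}; expected one of {SUPPORTED_BUILDS}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def position_string(self) -> str:
        """1-based inclusive display string, e.g. "chr8:11001-20000"."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass(frozen=True)
class AnnotatedInterval:
    """A GenomeInterval plus provenance: the (dataset, tissue) pairs it came from."""

    interval: GenomeInterval
    provenance: frozenset[tuple[str, str]] = frozenset()
    labels: tuple[tuple[str, str], ...] = ()

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def build(self) -> str:
        return self.interval.build

    def provenance_string(self) -> str:
        return ";".join(f"{d}|{t}" for d, t in sorted(self.provenance))


def overlaps(a: GenomeInterval, b: GenomeInterval) -> bool:
    """True iff the two intervals share at least one base.

    Half-open convention: bookended intervals ([0,10) vs [10,20)) do not
    overlap.  Comparing intervals from different builds is an error, never
    a silent False.
    """
    if a.build != b.build:
        raise BuildMismatchError(f"cannot compare {a.build} against {b.build}")
    if a.chrom != b.chrom:
        return False
    return max(a.start, b.start) < min(a.end, b.end)


def _as_annotated(iv: GenomeInterval | AnnotatedInterval) -> AnnotatedInterval:
    if isinstance(iv, AnnotatedInterval):
        return iv
    return AnnotatedInterval(interval=iv)


def merge_collapse(
    intervals: Iterable[GenomeInterval | AnnotatedInterval],
    gap: int = 0,
) -> list[AnnotatedInterval]:
    """Merge overlapping and bookended intervals, unioning provenance.

    Matches the default behaviour of ``bedtools merge``: at gap=0 adjacent
    (bookended) intervals are fused.  ``gap`` > 0 additionally bridges
    separations of up to ``gap`` bases.  Output is sorted by
    (chrom, start, end) and pairwise disjoint, with per-base coverage
    identical to the union of the inputs.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    items = sorted(
        (_as_annotated(iv) for iv in intervals),
        key=lambda a: (a.chrom, a.start, a.end),
    )
    if not items:
        return []
    builds = {a.build for a in items}
    if len(builds) > 1:
        raise BuildMismatchError(f"mixed builds in merge_collapse: {sorted(builds)}")

    out: list[AnnotatedInterval] = []
    cur_chrom, cur_start, cur_end = items[0].chrom, items[0].start, items[0].end
    cur_prov = set(items[0].provenance)
    cur_labels = dict(items[0].labels)
    build = items[0].build

    def flush() -> None:
        out.append(
            AnnotatedInterval(
                interval=GenomeInterval(cur_chrom, cur_start, cur_end, build),
                provenance=frozenset(cur_prov),
                labels=tuple(sorted(cur_labels.items())),
            )
        )

    for a in items[1:]:
        if a.chrom == cur_chrom and a.start <= cur_end + gap:
            cur_end = max(cur_end, a.end)
            cur_prov |= a.provenance
            cur_labels.update(dict(a.labels))
        else:
            flush()
            cur_chrom, cur_start, cur_end = a.chrom, a.start, a.end
            cur_prov = set(a.provenance)
            cur_labels = dict(a.labels)
    flush()
    return out


def total_span(intervals: Iterable[GenomeInterval | AnnotatedInterval]) -> int:
    """Number of distinct bases covered by the union of the intervals."""
    return sum(a.end - a.start for a in merge_collapse(intervals))


def intersection_span(
    a: Sequence[GenomeInterval | AnnotatedInterval],
    b: Sequence[GenomeInterval | AnnotatedInterval],
) -> int:
    """Bases covered by both interval sets (each unioned first)."""
    ma = merge_collapse(a)
    mb = merge_collapse(b)
    by_chrom: dict[str, list[AnnotatedInterval]] = {}
    for iv in mb:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    span = 0
    for iv in ma:
        for other in by_chrom.get(iv.chrom, []):
            lo = max(iv.start, other.start)
            hi = min(iv.end, other.end)
            if lo < hi:
                span += hi - lo
    return span


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _parse_provenance(token: str) -> frozenset[tuple[str, str]]:
    pairs = []
    for part in token.split(";"):
        if "|" in part:
            ds, _, tissue = part.partition("|")
            pairs.append((ds, tissue))
    return frozenset(pairs)


def read_bed(
    path: str | Path,
    build: str = "hg38",
    default_provenance: tuple[str, str] | None = None,
    normalize: bool = True,
) -> list[AnnotatedInterval]:
    """Read a BED3+ file (plain or gzip/bgzip) into annotated intervals.

    Column 4, when present and matching the ``dataset|tissue[;...]``
    dialect, is parsed as provenance; otherwise it is preserved under the
    ``name`` label.  Further columns are preserved as ``col5``, ``col6``...
    Track/browser/comment lines are skipped.  Malformed coordinates raise
    :class:`BedParseError` naming the offending line.
    """
    out: list[AnnotatedInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            if normalize:
                chrom = normalize_chrom(chrom)
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise BedParseError(
                    f"{path}: line {lineno}: invalid span [{start},{end})"
                )
            prov: frozenset[tuple[str, str]] = frozenset()
            labels: list[tuple[str, str]] = []
            if len(fields) >= 4 and fields[3]:
                prov = _parse_provenance(fields[3])
                if not prov:
                    labels.append(("name", fields[3]))
            if not prov and default_provenance is not None:
                prov = frozenset({default_provenance})
            for i, extra in enumerate(fields[4:], start=5):
                labels.append((f"col{i}", extra))
            out.append(
                AnnotatedInterval(
                    interval=GenomeInterval(chrom, start, end, build),
                    provenance=prov,
                    labels=tuple(labels),
                )
            )
    return out


def write_bed(
    intervals: Iterable[GenomeInterval | AnnotatedInterval],
    path: str | Path,
    ucsc_track_header: str | None = None,
) -> None:
    """Write sorted BED with provenance serialized into column 4.

    ``ucsc_track_header``, if given, is emitted verbatim as a
    ``track name=...`` custom-track line so the file can be pasted into a
    genome browser.
    """
    items = sorted(
        (_as_annotated(iv) for iv in intervals),
        key=lambda a: (a.chrom, a.start, a.end),
    )
    with open(path, "wt", encoding="utf-8") as fh:
        if ucsc_track_header is not None:
            fh.write(ucsc_track_header.rstrip("\n") + "\n")
        for a in items:
            name = a.provenance_string() or dict(a.labels).get("name", ".")
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{name}\n")
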