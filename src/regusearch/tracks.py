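"""Registry of tissue-specific regulatory tracks and data-preparation transforms.

A *track* is the set of regions of one regulator class (promoter, enhancer,
TFBS, repressor, insulator, or accessible chromatin) active in one tissue or
primary cell type, from one source dataset, in one genome build.  Tracks
are collapsed on ingest so their intervals are sorted and disjoint.

Data preparation mirrors the upstream pipelines these tracks come from:
biological replicates (including lifted-over coordinates) are collapsed by
union; CAGE-derived promoters are built from peak expression tables by
dropping peaks below a TPM threshold and extending survivors 200 bp
upstream; class-annotated ccRE BED files are split into one track per
regulator class.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .intervals import (
    AnnotatedInterval,
    GenomeInterval,
    merge_collapse,
    normalize_chrom,
    read_bed,
    total_span,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatorClass",
    "Track",
    "TrackKey",
    "CagePeak",
    "TrackStore",
    "TrackSummary",
    "make_track",
    "collapse_replicates",
    "promoters_from_cage",
    "split_ccres",
    "summarize_track",
    "load_cage_table",
]


class RegulatorClass(str, enum.Enum):
    PROMOTER = "promoter"
    ENHANCER = "enhancer"
    TFBS = "tfbs"
    REPRESSOR = "repressor"
    INSULATOR = "insulator"
    ACCESSIBLE_CHROMATIN = "accessible_chromatin"


TrackKey = tuple[str, str, RegulatorClass, str]  # (dataset, tissue, cls, build)


@dataclass(frozen=True)
class Track:
    dataset: str
    tissue: str
    cls: RegulatorClass
    build: str
    intervals: tuple[GenomeInterval, ...]

    @property
    def key(self) -> TrackKey:
        return (self.dataset, self.tissue, self.cls, self.build)

    def annotated(self) -> list[AnnotatedInterval]:
        prov = frozenset({(self.dataset, self.tissue)})
        return [AnnotatedInterval(interval=iv, provenance=prov) for iv in self.intervals]


def _collapse_plain(intervals: Iterable[GenomeInterval]) -> tuple[GenomeInterval, ...]:
    return tuple(a.interval for a in merge_collapse(intervals))


def make_track(
    dataset: str,
    tissue: str,
    cls: RegulatorClass | str,
    build: str,
    intervals: Iterable[GenomeInterval],
) -> Track:
    """Construct a track, collapsing its intervals to sorted disjoint form."""
    return Track(
        dataset=dataset,
        tissue=tissue,
        cls=RegulatorClass(cls),
        build=build,
        intervals=_collapse_plain(intervals),
    )


def collapse_replicates(tracks: list[Track]) -> Track:
    """Union biological replicates of the same (dataset, tissue, class, build).

    Per-base coverage of the result equals the union of the inputs.
    Mixing tracks with different keys is an error.
    """
    if not tracks:
        raise ValueError("collapse_replicates needs at least one track")
    keys = {t.key for t in tracks}
    if len(keys) > 1:
        raise ValueError(f"collapse_replicates over mixed keys: {sorted(map(str, keys))}")
    first = tracks[0]
    merged = _collapse_plain(iv for t in tracks for iv in t.intervals)
    return replace(first, intervals=merged)


@dataclass(frozen=True)
class CagePeak:
    """A CAGE (cap analysis of gene expression) peak with RLE-normalized TPM."""

    interval: GenomeInterval
    strand: str
    tpm: float
    sample: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"CAGE peak requires strand '+' or '-', got {self.strand!r}")
        if self.tpm < 0:
            raise ValueError("tpm must be >= 0")


def load_cage_table(path: str | Path, build: str = "hg38") -> list[CagePeak]:
    """Read a CAGE peak TSV with columns chrom, start, end, strand, tpm, sample."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str, "sample": str})
    required = ("chrom", "start", "end", "strand", "tpm")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"CAGE table {path} missing columns: {missing}")
    return [
        CagePeak(
            interval=GenomeInterval(
                normalize_chrom(str(r.chrom)), int(r.start), int(r.end), build
            ),
            strand=r.strand,
            tpm=float(r.tpm),
            sample=str(getattr(r, "sample", "")),
        )
        for r in df.itertuples(index=False)
    ]


def promoters_from_cage(
    peaks: list[CagePeak],
    tpm_threshold: float = 10.0,
    upstream_extension_bp: int = 200,
    dataset: str = "FANTOM_prom",
    tissue: str = "",
    build: str | None = None,
    strand_aware: bool = True,
) -> Track:
    """Derive a promoter track from CAGE peaks.

    Peaks with TPM strictly below ``tpm_threshold`` are dropped (a peak at
    exactly the threshold survives).  Each surviving peak — marking a
    transcription start site — is extended ``upstream_extension_bp`` bases
    upstream to take in the promoter region: against transcription
    direction when ``strand_aware`` (default), genomic-left otherwise.
    Extension is clamped at position 0 and the result collapsed.
    """
    surviving = [p for p in peaks if p.tpm >= tpm_threshold]
    if build is None:
        build = surviving[0].interval.build if surviving else "hg38"
    extended = []
    for p in surviving:
        iv = p.interval
        if strand_aware and p.strand == "-":
            ext = GenomeInterval(iv.chrom, iv.start, iv.end + upstream_extension_bp, iv.build)
        else:
            ext = GenomeInterval(
                iv.chrom, max(0, iv.start - upstream_extension_bp), iv.end, iv.build
            )
        extended.append(ext)
    return make_track(dataset, tissue, RegulatorClass.PROMOTER, build, extended)


# Token vocabulary for class-annotated ccRE BED files.  Keys are matched
# case-insensitively as substrings of the annotation token.
CCRE_CLASS_TOKENS: dict[str, RegulatorClass] = {
    "promoter-like": RegulatorClass.PROMOTER,
    "pls": RegulatorClass.PROMOTER,
    "enhancer-like": RegulatorClass.ENHANCER,
    "els": RegulatorClass.ENHANCER,
    "ctcf": RegulatorClass.INSULATOR,
    "insulator": RegulatorClass.INSULATOR,
    "dnase": RegulatorClass.ACCESSIBLE_CHROMATIN,
    "accessible": RegulatorClass.ACCESSIBLE_CHROMATIN,
}


def _classify_ccre_token(token: str) -> RegulatorClass | None:
    low = token.casefold()
    for needle, cls in CCRE_CLASS_TOKENS.items():
        if needle in low:
            return cls
    return None


def split_ccres(
    bed_path: str | Path,
    dataset: str,
    tissue: str,
    build: str = "hg38",
    class_column: int = 3,
) -> tuple[list[Track], int]:
    """Split a class-annotated ccRE BED into one track per regulator class.

    ``class_column`` is the 0-based index of the annotation column
    (default: the BED name field).  Records whose token is not recognized
    are skipped; their count is logged and returned.  A file in which no
    record is classifiable is an error.
    """
    records = read_bed(bed_path, build=build)
    by_class: dict[RegulatorClass, list[GenomeInterval]] = {}
    skipped = 0
    for rec in records:
        labels = dict(rec.labels)
        if class_column == 3:
            token = labels.get("name", "") or rec.provenance_string()
        else:
            token = labels.get(f"col{class_column + 1}", "")
        cls = _classify_ccre_token(token) if token else None
        if cls is None:
            skipped += 1
            continue
        by_class.setdefault(cls, []).append(rec.interval)
    if not by_class:
        raise ValueError(f"{bed_path}: no record carries a recognizable ccRE class token")
    if skipped:
        logger.warning("%s: skipped %d records with unrecognized class tokens", bed_path, skipped)
    tracks = [
        make_track(dataset, tissue, cls, build, ivs) for cls, ivs in sorted(by_class.items())
    ]
    return tracks, skipped


@dataclass(frozen=True)
class TrackSummary:
    region_count: int
    mean_size_bp: float
    total_span_bp: int


def summarize_track(track: Track) -> TrackSummary:
    """Region count / mean size / total span, on the collapsed intervals."""
    n = len(track.intervals)
    span = sum(iv.width for iv in track.intervals)
    return TrackSummary(
        region_count=n,
        mean_size_bp=span / n if n else 0.0,
        total_span_bp=span,
    )


class TrackStore:
    """In-memory registry of tracks keyed by (dataset, tissue, class, build)."""

    def __init__(self) -> None:
        self._tracks: dict[TrackKey, Track] = {}

    def __len__(self) -> int:
        return len(self._tracks)

    def __iter__(self):
        return iter(self._tracks.values())

    def add(self, track: Track, replace_existing: bool = False) -> None:
        if track.key in self._tracks and not replace_existing:
            raise KeyError(f"track already registered for key {track.key}; pass replace to overwrite")
        self._tracks[track.key] = track

    def register_track(
        self,
        dataset: str,
        tissue: str,
        cls: RegulatorClass | str,
        build: str,
        bed_path: str | Path,
        replace_existing: bool = False,
    ) -> Track:
        """Load a BED file as a track, collapsing its intervals on ingest."""
        records = read_bed(bed_path, build=build)
        track = make_track(dataset, tissue, cls, build, (r.interval for r in records))
        self.add(track, replace_existing=replace_existing)
        return track

    def get(self, dataset: str, tissue: str, cls: RegulatorClass | str, build: str) -> Track | None:
        return self._tracks.get((dataset, tissue, RegulatorClass(cls), build))

    def tracks(
        self,
        dataset: str | None = None,
        tissue: str | None = None,
        cls: RegulatorClass | str | None = None,
        build: str | None = None,
    ) -> list[Track]:
        cls = RegulatorClass(cls) if cls is not None else None
        return [
            t
            for t in self._tracks.values()
            if (dataset is None or t.dataset == dataset)
            and (tissue is None or t.tissue == tissue)
            and (cls is None or t.cls == cls)
            and (build is None or t.build == build)
        ]

    def datasets(self) -> list[str]:
        return sorted({t.dataset for t in self._tracks.values()})

    def available_tissues(
        self,
        cls: RegulatorClass | str | None = None,
        dataset: str | None = None,
    ) -> list[str]:
        return sorted({t.tissue for t in self.tracks(dataset=dataset, cls=cls)})

    def tissue_class_availability(self) -> dict[str, set[RegulatorClass]]:
        """Which regulator classes have data for each tissue (availability grid)."""
        grid: dict[str, set[RegulatorClass]] = {}
        for t in self._tracks.values():
            grid.setdefault(t.tissue, set()).add(t.cls)
        return grid

    # -- manifest persistence ----------------------------------------------

    def to_manifest(self, path: str | Path, bed_dir: str | Path) -> None:
        """Write each track as a BED file plus a YAML manifest listing them."""
        import os

        from .intervals import write_bed

        path = Path(path)
        bed_dir = Path(bed_dir)
        bed_dir.mkdir(parents=True, exist_ok=True)
        entries = []
        for t in sorted(self._tracks.values(), key=lambda t: t.key):
            fname = f"{t.dataset}__{t.tissue}__{t.cls.value}__{t.build}.bed".replace(" ", "_")
            write_bed(t.annotated(), bed_dir / fname)
            entries.append(
                {
                    "dataset": t.dataset,
                    "tissue": t.tissue,
                    "cls": t.cls.value,
                    "build": t.build,
                    "path": os.path.relpath(bed_dir / fname, path.parent),
                }
            )
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump({"tracks": entries}, fh, sort_keys=False)

    @classmethod
    def from_manifest(cls, path: str | Path) -> "TrackStore":
        path = Path(path)
        with open(path, "rt", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        store = cls()
        for entry in doc.get("tracks", []):
            bed_path = Path(entry["path"])
            if not bed_path.is_absolute():
                bed_path = path.parent / bed_path
            store.register_track(
                dataset=entry["dataset"],
                tissue=entry["tissue"],
                cls=entry["cls"],
                build=entry["build"],
                bed_path=bed_path,
            )
        return store
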