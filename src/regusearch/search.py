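"""Tissue-filtered, TSS-anchored search for regulatory regions.

For each enabled cis-regulatory dataset, candidate regions are the regions
of that dataset's tracks for the queried tissues.  A candidate enters the
result when

1. it overlaps a TSS window of one of the target genes, built with the
   dataset's upstream/downstream spans, and
2. (*active-in-any*) it is present in at least one target-tissue track of
   the dataset, or (*active-in-all*) it is present in **every available**
   target-tissue track of the dataset.

"Present in" a tissue track means >= 1 bp overlap with that track —
datasets call region boundaries differently between tissues, so requiring
exact coordinate identity would be too strict.  A queried tissue with no
track in a dataset does not count against the *all* condition; it is
reported as missing instead.

miRNA loci selected by :func:`regusearch.mirna.active_mirna_loci` are
added, and everything is merged and collapsed into disjoint intervals,
each carrying the (dataset, tissue) pairs that produced it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .genes import GeneTable, TSSWindow
from .intervals import (
    AnnotatedInterval,
    GenomeInterval,
    merge_collapse,
    write_bed,
)
from .mirna import InteractionRegistry, MiRNALocus, active_mirna_loci
from .tracks import Track, TrackStore

logger = logging.getLogger(__name__)

__all__ = [
    "DatasetConfig",
    "MirnaConfig",
    "SearchQuery",
    "SearchResult",
    "SearchEngine",
]

MODES = ("any", "all")


@dataclass(frozen=True)
class DatasetConfig:
    """Per-dataset search parameters: TSS window spans and activity mode."""

    enabled: bool = True
    upstream_bp: int = 50_000
    downstream_bp: int = 50_000
    mode: str = "any"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValueError("window spans must be >= 0")


@dataclass(frozen=True)
class MirnaConfig:
    enabled: bool = False
    source: str = "both"  # experimental | predicted | both
    evidence_whitelist: frozenset[str] | None = None
    chromatin_datasets: tuple[str, ...] | None = None


@dataclass(frozen=True)
class SearchQuery:
    build: str
    genes: tuple[str, ...]
    tissues: tuple[str, ...]
    dataset_configs: dict[str, DatasetConfig]
    mirna_config: MirnaConfig = MirnaConfig()
    strand_aware_windows: bool = True

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("query requires at least one gene")
        if not self.tissues:
            raise ValueError("query requires at least one tissue")
        enabled = [d for d, c in self.dataset_configs.items() if c.enabled]
        if not enabled and not self.mirna_config.enabled:
            raise ValueError("query requires at least one enabled dataset or the miRNA source")


@dataclass
class SearchResult:
    intervals: list[AnnotatedInterval]
    per_dataset: dict[str, list[AnnotatedInterval]] = field(default_factory=dict)

    @property
    def region_count(self) -> int:
        return len(self.intervals)

    @property
    def total_span_bp(self) -> int:
        return sum(a.end - a.start for a in self.intervals)

    @property
    def stats(self) -> dict[str, int]:
        return {"region_count": self.region_count, "total_span_bp": self.total_span_bp}

    def to_bed(self, path: str | Path, ucsc_track_header: str | None = None) -> None:
        write_bed(self.intervals, path, ucsc_track_header=ucsc_track_header)

    def to_table(self) -> pd.DataFrame:
        """One row per (interval, provenance pair)."""
        rows = []
        for a in self.intervals:
            for ds, tissue in sorted(a.provenance):
                rows.append(
                    {
                        "chrom": a.chrom,
                        "start": a.start,
                        "end": a.end,
                        "dataset": ds,
                        "tissue": tissue,
                    }
                )
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "dataset", "tissue"])

    def ucsc_payload(self, track_name: str = "regusearch") -> dict[str, object]:
        """Position string of the spanning range plus custom-track lines."""
        if not self.intervals:
            return {"position": "", "track_lines": [f'track name="{track_name}"']}
        first_chrom = self.intervals[0].chrom
        same = [a for a in self.intervals if a.chrom == first_chrom]
        span = GenomeInterval(
            first_chrom,
            min(a.start for a in same),
            max(a.end for a in same),
            self.intervals[0].build,
        )
        lines = [f'track name="{track_name}"']
        lines += [
            f"{a.chrom}\t{a.start}\t{a.end}\t{a.provenance_string() or '.'}"
            for a in self.intervals
        ]
        return {"position": span.position_string(), "track_lines": lines}


def _tree(intervals) -> dict[str, IntervalTree]:
    by_chrom: dict[str, IntervalTree] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return by_chrom

def _hits(trees: dict[str, IntervalTree], iv: GenomeInterval) -> bool:
    tree = trees.get(iv.chrom)
    return bool(tree is not None and tree.overlap(iv.start, iv.end))


class SearchEngine:
    """Binds a track store, a gene table and (optionally) miRNA data."""

    def __init__(
        self,
        store: TrackStore,
        gene_table: GeneTable,
        mirna_registry: InteractionRegistry | None = None,
        mirna_loci: dict[str, MiRNALocus] | None = None,
    ):
        self.store = store
        self.gene_table = gene_table
        self.mirna_registry = mirna_registry
        self.mirna_loci = mirna_loci or {}

    # -- single-dataset search ---------------------------------------------

    def search_cis(self, dataset: str, query: SearchQuery) -> list[AnnotatedInterval]:
        """Regions of one dataset passing the TSS-window and activity-mode test."""
        cfg = query.dataset_configs[dataset]
        if dataset not in self.store.datasets():
            raise KeyError(f"unknown dataset id {dataset!r}")
        tissue_tracks: dict[str, list[Track]] = {}
        for tissue in query.tissues:
            tracks = self.store.tracks(dataset=dataset, tissue=tissue, build=query.build)
            if tracks:
                tissue_tracks[tissue] = tracks
            else:
                logger.warning("dataset %s has no track for tissue %r", dataset, tissue)
        if not tissue_tracks:
            return []

        windows, unknown = self.gene_table.tss_windows_for_genes(
            list(query.genes),
            cfg.upstream_bp,
            cfg.downstream_bp,
            strand_aware=query.strand_aware_windows,
        )
        if unknown:
            logger.warning("unknown gene symbols: %s", ", ".join(unknown))
        window_trees = _tree(w.interval for w in windows)

        track_trees = {
            tissue: _tree(iv for t in tracks for iv in t.intervals)
            for tissue, tracks in tissue_tracks.items()
        }

        candidates = sorted(
            {iv for tracks in tissue_tracks.values() for t in tracks for iv in t.intervals}
        )
        out: list[AnnotatedInterval] = []
        for region in candidates:
            if not _hits(window_trees, region):
                continue
            supporting = [
                tissue for tissue, trees in track_trees.items() if _hits(trees, region)
            ]
            if cfg.mode == "all" and len(supporting) < len(tissue_tracks):
                continue
            # mode "any": region came from some queried tissue track, so
            # supporting is non-empty by construction
            out.append(
                AnnotatedInterval(
                    interval=region,
                    provenance=frozenset((dataset, t) for t in supporting),
                )
            )
        return out

    # -- full protocol -----------------------------------------------------

    def run_search(self, query: SearchQuery) -> SearchResult:
        """Execute the full protocol and merge everything into one result."""
        found, unknown = self.gene_table.resolve(list(query.genes))
        if not found:
            from .genes import UnknownGenesError

            raise UnknownGenesError(unknown)

        per_dataset: dict[str, list[AnnotatedInterval]] = {}
        any_track = False
        for dataset, cfg in sorted(query.dataset_configs.items()):
            if not cfg.enabled:
                continue
            regions = self.search_cis(dataset, query)
            per_dataset[dataset] = regions
            if any(
                self.store.tracks(dataset=dataset, tissue=t, build=query.build)
                for t in query.tissues
            ):
                any_track = True

        mirna_regions: list[AnnotatedInterval] = []
        mc = query.mirna_config
        if mc.enabled and self.mirna_registry is not None:
            mirna_regions = active_mirna_loci(
                genes=list(query.genes),
                tissues=list(query.tissues),
                registry=self.mirna_registry,
                loci=self.mirna_loci,
                store=self.store,
                build=query.build,
                source=mc.source,
                evidence_whitelist=set(mc.evidence_whitelist) if mc.evidence_whitelist else None,
                chromatin_datasets=list(mc.chromatin_datasets) if mc.chromatin_datasets else None,
            )
            per_dataset["miRNA"] = mirna_regions
            if mirna_regions:
                any_track = True

        if not any_track and not mc.enabled:
            raise ValueError(
                f"no dataset has tracks for any queried tissue {list(query.tissues)}"
            )

        merged = merge_collapse(
            [a for regions in per_dataset.values() for a in regions]
        )
        return SearchResult(intervals=merged, per_dataset=per_dataset)
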