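"""miRNA–gene interactions and tissue-restricted miRNA locus selection.

Interactions come in two flavours: experimentally validated (miRTarBase-
shaped tables) and computationally predicted (miRWalk-shaped tables).
Predicted interactions are kept only when they target the 3'-UTR of the
gene.  Because neither interaction database is tissue-specific, tissue
restriction is imposed indirectly: a miRNA locus enters a search result
only if its transcript overlaps an accessible-chromatin region active in
one of the target tissues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .intervals import AnnotatedInterval, GenomeInterval, overlaps, read_bed
from .tracks import RegulatorClass, TrackStore

logger = logging.getLogger(__name__)

__all__ = [
    "MiRNAInteraction",
    "MiRNALocus",
    "InteractionRegistry",
    "load_interactions",
    "load_mirna_loci",
    "active_mirna_loci",
]

SOURCES = ("experimental", "predicted")


@dataclass(frozen=True)
class MiRNAInteraction:
    mirna_id: str
    gene: str
    source: str  # "experimental" | "predicted"
    confidence: str = ""
    region: str = ""


@dataclass(frozen=True)
class MiRNALocus:
    mirna_id: str
    interval: GenomeInterval


class InteractionRegistry:
    """miRNA–gene interactions, queryable by target gene (case-insensitive)."""

    def __init__(self, evidence_priority: list[str] | None = None):
        # higher-priority tags appear earlier in evidence_priority
        self._priority = {tag: i for i, tag in enumerate(evidence_priority or [])}
        self._by_pair: dict[tuple[str, str, str], MiRNAInteraction] = {}
        self.dropped_non_3utr = 0

    def _rank(self, tag: str) -> tuple[int, str]:
        # unranked tags sort after all ranked ones, then lexicographically
        return (self._priority.get(tag, len(self._priority)), tag)

    def add(self, rec: MiRNAInteraction) -> None:
        if rec.source not in SOURCES:
            raise ValueError(f"interaction source must be one of {SOURCES}, got {rec.source!r}")
        if rec.source == "predicted" and rec.region != "3UTR":
            self.dropped_non_3utr += 1
            return
        key = (rec.mirna_id, rec.gene.casefold(), rec.source)
        prev = self._by_pair.get(key)
        if prev is None or self._rank(rec.confidence) < self._rank(prev.confidence):
            self._by_pair[key] = rec

    def load(self, path: str | Path, source: str) -> int:
        """Load an interaction TSV; returns the number of records retained.

        Required columns: ``mirna_id``, ``gene``, ``evidence``; predicted
        tables additionally require ``region`` (only "3UTR" rows are kept,
        dropped rows are counted and logged).
        """
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        required = ["mirna_id", "gene", "evidence"]
        if source == "predicted":
            required.append("region")
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"interaction table {path} missing columns: {missing}")
        before = len(self._by_pair)
        dropped_before = self.dropped_non_3utr
        for r in df.itertuples(index=False):
            self.add(
                MiRNAInteraction(
                    mirna_id=r.mirna_id,
                    gene=r.gene,
                    source=source,
                    confidence=r.evidence,
                    region=getattr(r, "region", ""),
                )
            )
        dropped = self.dropped_non_3utr - dropped_before
        if dropped:
            logger.info("%s: dropped %d predicted interactions not targeting the 3'-UTR", path, dropped)
        return len(self._by_pair) - before

    def interactions_for_gene(
        self,
        gene: str,
        source: str = "both",
        evidence_whitelist: set[str] | None = None,
    ) -> list[MiRNAInteraction]:
        out = []
        for (mirna, g, src), rec in self._by_pair.items():
            if g != gene.casefold():
                continue
            if source != "both" and src != source:
                continue
            if evidence_whitelist is not None and rec.confidence not in evidence_whitelist:
                continue
            out.append(rec)
        return sorted(out, key=lambda r: (r.mirna_id, r.source))

    def records(self) -> list[MiRNAInteraction]:
        return [self._by_pair[k] for k in sorted(self._by_pair)]

    def __len__(self) -> int:
        return len(self._by_pair)


def load_interactions(
    path: str | Path,
    source: str,
    evidence_priority: list[str] | None = None,
) -> InteractionRegistry:
    reg = InteractionRegistry(evidence_priority=evidence_priority)
    reg.load(path, source)
    return reg


def load_mirna_loci(path: str | Path, build: str = "hg38") -> dict[str, MiRNALocus]:
    """Read miRNA transcript coordinates from a BED file (miRNA id in column 4)."""
    loci: dict[str, MiRNALocus] = {}
    for rec in read_bed(path, build=build):
        name = dict(rec.labels).get("name") or rec.provenance_string()
        if not name:
            continue
        loci[name] = MiRNALocus(mirna_id=name, interval=rec.interval)
    return loci


def active_mirna_loci(
    genes: list[str],
    tissues: list[str],
    registry: InteractionRegistry,
    loci: dict[str, MiRNALocus],
    store: TrackStore,
    build: str,
    source: str = "both",
    evidence_whitelist: set[str] | None = None,
    chromatin_datasets: list[str] | None = None,
    mirna_dataset_label: str = "miRNA",
) -> list[AnnotatedInterval]:
    """Loci of miRNAs that target a query gene *and* sit in open chromatin.

    A miRNA transcript is included when (1) it interacts with at least one
    target gene under the source/evidence criteria and (2) its span
    overlaps (>= 1 bp) an accessible-chromatin track of one of the target
    tissues.  Provenance records the miRNA dataset label together with
    each tissue whose open-chromatin track supports the locus.
    ``chromatin_datasets`` optionally restricts which datasets' chromatin
    tracks may vouch for activity.
    """
    chrom_tracks = [
        t
        for t in store.tracks(cls=RegulatorClass.ACCESSIBLE_CHROMATIN, build=build)
        if t.tissue in set(tissues)
        and (chromatin_datasets is None or t.dataset in set(chromatin_datasets))
    ]
    if not chrom_tracks:
        logger.warning(
            "no accessible-chromatin tracks for tissues %s; miRNA result is empty", tissues
        )
        return []

    interacting: set[str] = set()
    for gene in genes:
        for rec in registry.interactions_for_gene(
            gene, source=source, evidence_whitelist=evidence_whitelist
        ):
            if rec.mirna_id not in loci:
                logger.warning("miRNA %s has interactions but no known locus; skipped", rec.mirna_id)
                continue
            interacting.add(rec.mirna_id)

    out: list[AnnotatedInterval] = []
    for mirna_id in sorted(interacting):
        locus = loci[mirna_id]
        supporting = set()
        for track in chrom_tracks:
            if any(overlaps(locus.interval, iv) for iv in track.intervals):
                supporting.add((mirna_dataset_label, track.tissue))
        if supporting:
            out.append(
                AnnotatedInterval(
                    interval=locus.interval,
                    provenance=frozenset(supporting),
                    labels=(("mirna_id", mirna_id),),
                )
            )
    return out
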