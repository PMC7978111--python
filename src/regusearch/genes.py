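"""Transcript registry and TSS-window construction.

Transcripts are loaded from a genePred-style tab-separated table (the shape
of a UCSC ``ncbiRefSeq`` export): one row per transcript, with the gene
symbol in ``name2``.  All transcripts of a gene are kept — regulatory
search anchors windows on every annotated TSS, not just a canonical one.

A TSS window extends a configurable number of bases upstream and
downstream of the first transcribed base, in transcription direction by
default ("upstream of the TSS" in the biological sense).  For comparisons
with strand-agnostic pipelines a genomic-left interpretation can be
selected instead.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .intervals import GenomeInterval

__all__ = [
    "Transcript",
    "TSSWindow",
    "GeneTable",
    "load_gene_table",
    "tss_window",
    "UnknownGenesError",
]

REQUIRED_COLUMNS = ("name", "chrom", "strand", "txStart", "txEnd", "name2")


class UnknownGenesError(KeyError):
    """Raised when none of the requested gene symbols resolve."""

    def __init__(self, symbols: list[str]):
        super().__init__(f"no transcripts found for any of: {', '.join(symbols)}")
        self.symbols = symbols


@dataclass(frozen=True)
class Transcript:
    gene: str
    tx_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    build: str = "hg38"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"transcript span invalid: [{self.tx_start},{self.tx_end})")

    @property
    def tss(self) -> int:
        """0-based genomic position of the first transcribed base."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.tx_start, self.tx_end, self.build)


@dataclass(frozen=True)
class TSSWindow:
    interval: GenomeInterval
    source: Transcript
    upstream_bp: int
    downstream_bp: int


def tss_window(
    t: Transcript,
    upstream_bp: int,
    downstream_bp: int,
    strand_aware: bool = True,
) -> TSSWindow:
    """Window around the TSS, clamped at position 0.

    The TSS base itself is always included, so a 0/0 window is a 1-bp
    interval.  With ``strand_aware`` (default), upstream means against the
    direction of transcription; otherwise upstream is genomic-left.
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise ValueError("window spans must be >= 0")
    tss = t.tss
    if strand_aware and t.strand == "-":
        start = max(0, tss - downstream_bp)
        end = tss + upstream_bp + 1
    else:
        start = max(0, tss - upstream_bp)
        end = tss + downstream_bp + 1
    return TSSWindow(
        interval=GenomeInterval(t.chrom, start, end, t.build),
        source=t,
        upstream_bp=upstream_bp,
        downstream_bp=downstream_bp,
    )


class GeneTable:
    """Registry of transcripts, queryable by case-insensitive HGNC symbol."""

    def __init__(self, transcripts: list[Transcript]):
        if not transcripts:
            raise ValueError("gene table contains zero transcripts")
        self._transcripts = list(transcripts)
        self._by_symbol: dict[str, list[Transcript]] = {}
        for t in transcripts:
            self._by_symbol.setdefault(t.gene.casefold(), []).append(t)

    def __len__(self) -> int:
        return len(self._transcripts)

    @property
    def genes(self) -> list[str]:
        seen: dict[str, str] = {}
        for t in self._transcripts:
            seen.setdefault(t.gene.casefold(), t.gene)
        return sorted(seen.values())

    def transcripts(self, symbol: str) -> list[Transcript]:
        return list(self._by_symbol.get(symbol.casefold(), []))

    def resolve(self, symbols: list[str]) -> tuple[dict[str, list[Transcript]], list[str]]:
        """Map each symbol to its transcripts; also return symbols with no match."""
        found: dict[str, list[Transcript]] = {}
        unknown: list[str] = []
        for s in symbols:
            txs = self.transcripts(s)
            if txs:
                found[s] = txs
            else:
                unknown.append(s)
        return found, unknown

    def tss_windows_for_genes(
        self,
        symbols: list[str],
        upstream_bp: int,
        downstream_bp: int,
        strand_aware: bool = True,
    ) -> tuple[list[TSSWindow], list[str]]:
        """One window per transcript of each resolved gene.

        Unknown symbols are returned alongside the windows; if *no* symbol
        resolves, :class:`UnknownGenesError` lists them all.
        """
        if not symbols:
            raise ValueError("at least one gene symbol required")
        found, unknown = self.resolve(symbols)
        if not found:
            raise UnknownGenesError(unknown)
        windows = [
            tss_window(t, upstream_bp, downstream_bp, strand_aware=strand_aware)
            for txs in found.values()
            for t in txs
        ]
        return windows, unknown

    # -- single-file relational persistence ---------------------------------

    def to_sqlite(self, path: str | Path) -> None:
        con = sqlite3.connect(path)
        try:
            con.execute("DROP TABLE IF EXISTS transcripts")
            con.execute(
                "CREATE TABLE transcripts "
                "(gene TEXT, tx_id TEXT, chrom TEXT, strand TEXT, "
                "tx_start INTEGER, tx_end INTEGER, build TEXT)"
            )
            con.executemany(
                "INSERT INTO transcripts VALUES (?,?,?,?,?,?,?)",
                [
                    (t.gene, t.tx_id, t.chrom, t.strand, t.tx_start, t.tx_end, t.build)
                    for t in self._transcripts
                ],
            )
            con.commit()
        finally:
            con.close()

    @classmethod
    def from_sqlite(cls, path: str | Path) -> "GeneTable":
        con = sqlite3.connect(path)
        try:
            rows = con.execute(
                "SELECT gene, tx_id, chrom, strand, tx_start, tx_end, build "
                "FROM transcripts"
            ).fetchall()
        finally:
            con.close()
        return cls([Transcript(*row) for row in rows])


def load_gene_table(path: str | Path, build: str = "hg38") -> GeneTable:
    """Load a genePred-style TSV (header row; '#' prefix on header tolerated)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lstrip("#") for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene table {path} missing required columns: {missing}")
    if len(df) == 0:
        raise ValueError(f"gene table {path} has zero rows")
    transcripts = [
        Transcript(
            gene=row.name2,
            tx_id=row.name,
            chrom=row.chrom,
            strand=row.strand,
            tx_start=int(row.txStart),
            tx_end=int(row.txEnd),
            build=build,
        )
        for row in df.itertuples(index=False)
    ]
    return GeneTable(transcripts)
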