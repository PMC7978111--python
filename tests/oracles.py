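"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's interval machinery: coverage is
computed base by base with numpy boolean masks, and the search protocol is
re-checked literally — every candidate region against every TSS window and
every tissue track by pairwise overlap — with no interval index.
"""

from __future__ import annotations

import numpy as np


def coverage_mask(intervals, length: int, chrom: str) -> np.ndarray:
    """Per-base boolean coverage of one chromosome."""
    mask = np.zeros(length, dtype=bool)
    for iv in intervals:
        c = getattr(iv, "chrom", None) or iv.interval.chrom
        s = getattr(iv, "start", None)
        e = getattr(iv, "end", None)
        if s is None:
            s, e = iv.interval.start, iv.interval.end
        if c == chrom:
            mask[s:e] = True
    return mask


def pair_overlaps(c1, s1, e1, c2, s2, e2) -> bool:
    return c1 == c2 and max(s1, s2) < min(e1, e2)


def brute_force_tss_windows(transcripts, up: int, down: int):
    """(chrom, start, end) windows, strand-aware upstream, clamped at 0."""
    windows = []
    for t in transcripts:
        if t.strand == "+":
            tss = t.tx_start
            windows.append((t.chrom, max(0, tss - up), tss + down + 1))
        else:
            tss = t.tx_end - 1
            windows.append((t.chrom, max(0, tss - down), tss + up + 1))
    return windows


def brute_force_cis(store, gene_table, dataset, genes, tissues, up, down, mode, build):
    """Literal re-check of the inclusion conditions for one dataset.

    Returns the list of (chrom, start, end) regions selected.
    """
    transcripts = [t for g in genes for t in gene_table.transcripts(g)]
    windows = brute_force_tss_windows(transcripts, up, down)

    tissue_regions = {}
    for tissue in tissues:
        regions = [
            (iv.chrom, iv.start, iv.end)
            for trk in store.tracks(dataset=dataset, tissue=tissue, build=build)
            for iv in trk.intervals
        ]
        if regions:
            tissue_regions[tissue] = regions
    if not tissue_regions:
        return []

    candidates = sorted({r for regions in tissue_regions.values() for r in regions})
    selected = []
    for c, s, e in candidates:
        if not any(pair_overlaps(c, s, e, wc, ws, we) for wc, ws, we in windows):
            continue
        present_in = [
            tissue
            for tissue, regions in tissue_regions.items()
            if any(pair_overlaps(c, s, e, rc, rs, re_) for rc, rs, re_ in regions)
        ]
        if mode == "any" and len(present_in) >= 1:
            selected.append((c, s, e))
        elif mode == "all" and len(present_in) == len(tissue_regions):
            selected.append((c, s, e))
    return selected


def brute_force_mirna(registry, loci, store, genes, tissues, build, source="both"):
    """Literal re-check of the miRNA branch; returns (chrom, start, end) loci."""
    chrom_regions = []
    for trk in store.tracks(cls="accessible_chromatin", build=build):
        if trk.tissue in tissues:
            chrom_regions += [(iv.chrom, iv.start, iv.end) for iv in trk.intervals]
    selected = []
    seen = set()
    for rec in registry.records():
        if source != "both" and rec.source != source:
            continue
        if rec.gene.casefold() not in {g.casefold() for g in genes}:
            continue
        locus = loci.get(rec.mirna_id)
        if locus is None or rec.mirna_id in seen:
            continue
        iv = locus.interval
        if any(pair_overlaps(iv.chrom, iv.start, iv.end, c, s, e) for c, s, e in chrom_regions):
            seen.add(rec.mirna_id)
            selected.append((iv.chrom, iv.start, iv.end))
    return selected


def brute_force_vcf_keep(records, regions, build) -> list[bool]:
    """Per-record keep decision: REF span vs every region, pairwise."""
    keep = []
    for rec in records:
        chrom = rec.chrom if rec.chrom.startswith("chr") else "chr" + rec.chrom
        s = rec.pos - 1
        e = s + len(rec.ref)
        keep.append(
            any(
                pair_overlaps(chrom, s, e, r.chrom, r.start, r.end)
                for r in regions
            )
        )
    return keep
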