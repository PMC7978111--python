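"""Randomized toy stores shared by search and acceptance tests."""

from __future__ import annotations

import numpy as np

from regusearch.genes import GeneTable, Transcript
from regusearch.intervals import GenomeInterval
from regusearch.search import DatasetConfig, SearchEngine, SearchQuery
from regusearch.tracks import TrackStore, make_track

BUILD = "hg38"
CHROM_LEN = 200_000


def random_world(seed, n_datasets=3, n_tissues=4, regions_per_track=20, chrom_len=CHROM_LEN):
    """A seeded store of n_datasets x n_tissues tracks plus 3 genes on chr1.

    Some dataset x tissue pairs are left trackless so the available-track
    quantification of all-mode is exercised.
    """
    rng = np.random.default_rng(seed)
    genes = []
    for i in range(3):
        strand = "+" if i % 2 == 0 else "-"
        start = int(rng.integers(30_000, chrom_len - 50_000))
        genes.append(
            Transcript(
                f"G{i}", f"NM_{i}", "chr1", strand, start,
                start + int(rng.integers(5_000, 15_000)), BUILD,
            )
        )
    table = GeneTable(genes)
    store = TrackStore()
    datasets = [f"ds{i}" for i in range(n_datasets)]
    tissues = [f"t{i}" for i in range(n_tissues)]
    classes = ["enhancer", "promoter", "accessible_chromatin"]
    for di, ds in enumerate(datasets):
        for tissue in tissues:
            if rng.random() < 0.15:
                continue
            starts = rng.integers(0, chrom_len - 600, size=regions_per_track)
            widths = rng.integers(50, 600, size=regions_per_track)
            store.add(
                make_track(
                    ds, tissue, classes[di % 3], BUILD,
                    [
                        GenomeInterval("chr1", int(s), int(s + w), BUILD)
                        for s, w in zip(starts, widths)
                    ],
                )
            )
    return store, table, datasets, tissues


def run_query(store, table, datasets, tissues, mode, up, down, genes=("G0", "G1", "G2")):
    engine = SearchEngine(store, table)
    q = SearchQuery(
        build=BUILD,
        genes=tuple(genes),
        tissues=tuple(tissues),
        dataset_configs={
            d: DatasetConfig(upstream_bp=up, downstream_bp=down, mode=mode) for d in datasets
        },
    )
    return engine.run_search(q)
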