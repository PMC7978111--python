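"""Search protocol: TSS-window anchoring, any/all tissue modes, merging."""

import numpy as np
import pytest

from regusearch.genes import GeneTable, Transcript
from regusearch.intervals import GenomeInterval
from regusearch.search import DatasetConfig, MirnaConfig, SearchEngine, SearchQuery
from regusearch.tracks import TrackStore, make_track

from oracles import brute_force_cis, brute_force_mirna, coverage_mask
from worlds import random_world, run_query

BUILD = "hg38"


def gi(chrom, start, end):
    return GenomeInterval(chrom, start, end, BUILD)


@pytest.fixture()
def simple():
    """One '+' gene at TSS 10_000; dataset 'ds' with a region active in tissue A only."""
    genes = GeneTable(
        [Transcript("BLK", "NM_1", "chr1", "+", 10_000, 30_000, BUILD)]
    )
    store = TrackStore()
    store.add(make_track("ds", "A", "enhancer", BUILD, [gi("chr1", 9_000, 9_400)]))
    store.add(make_track("ds", "B", "enhancer", BUILD, [gi("chr1", 50_000, 50_100)]))
    return store, genes


def query(tissues, mode="any", up=2_000, down=2_000, datasets=("ds",), **kw):
    return SearchQuery(
        build=BUILD,
        genes=("BLK",),
        tissues=tuple(tissues),
        dataset_configs={d: DatasetConfig(upstream_bp=up, downstream_bp=down, mode=mode) for d in datasets},
        **kw,
    )


class TestCisSemantics:
    def test_any_mode_includes_single_tissue_region_with_provenance(self, simple):
        store, genes = simple
        engine = SearchEngine(store, genes)
        out = engine.search_cis("ds", query(["A", "B"], mode="any"))
        assert [(a.start, a.end) for a in out] == [(9_000, 9_400)]
        assert out[0].provenance == {("ds", "A")}

    def test_all_mode_excludes_region_missing_from_one_track(self, simple):
        store, genes = simple
        engine = SearchEngine(store, genes)
        assert engine.search_cis("ds", query(["A", "B"], mode="all")) == []

    def test_all_mode_quantifies_over_available_tracks_only(self, simple):
        # tissue C has no track in this dataset: a region active in A alone passes
        store, genes = simple
        engine = SearchEngine(store, genes)
        out = engine.search_cis("ds", query(["A", "C"], mode="all"))
        assert [(a.start, a.end) for a in out] == [(9_000, 9_400)]

    def test_region_outside_tss_window_excluded(self, simple):
        store, genes = simple
        engine = SearchEngine(store, genes)
        assert engine.search_cis("ds", query(["A"], up=100, down=100)) == []

    def test_boundary_inexact_presence_check(self):
        # tissue tracks call the same element with shifted boundaries:
        # >=1 bp overlap is enough for "present in"
        genes = GeneTable([Transcript("BLK", "NM_1", "chr1", "+", 10_000, 30_000, BUILD)])
        store = TrackStore()
        store.add(make_track("ds", "A", "enhancer", BUILD, [gi("chr1", 9_000, 9_400)]))
        store.add(make_track("ds", "B", "enhancer", BUILD, [gi("chr1", 9_300, 9_600)]))
        engine = SearchEngine(store, genes)
        out = engine.search_cis("ds", query(["A", "B"], mode="all"))
        assert {(a.start, a.end) for a in out} == {(9_000, 9_400), (9_300, 9_600)}
        assert all(a.provenance == {("ds", "A"), ("ds", "B")} for a in out)

    def test_unknown_dataset_raises(self, simple):
        store, genes = simple
        engine = SearchEngine(store, genes)
        with pytest.raises(KeyError, match="nope"):
            engine.search_cis("nope", query(["A"], datasets=("nope",)))

    def test_no_track_for_any_queried_tissue_empty(self, simple):
        store, genes = simple
        engine = SearchEngine(store, genes)
        assert engine.search_cis("ds", query(["X", "Y"])) == []


class TestRunSearch:
    def test_degenerate_single_dataset_equals_collapsed_cis(self, simple):
        store, genes = simple
        engine = SearchEngine(store, genes)
        q = query(["A"])
        res = engine.run_search(q)
        cis = engine.search_cis("ds", q)
        assert [(a.start, a.end) for a in res.intervals] == [(a.start, a.end) for a in cis]

    def test_overlapping_datasets_merge_with_joint_provenance(self):
        genes = GeneTable([Transcript("BLK", "NM_1", "chr1", "+", 10_000, 30_000, BUILD)])
        store = TrackStore()
        store.add(make_track("d1", "A", "enhancer", BUILD, [gi("chr1", 9_000, 9_400)]))
        store.add(make_track("d2", "A", "promoter", BUILD, [gi("chr1", 9_200, 9_600)]))
        engine = SearchEngine(store, genes)
        res = engine.run_search(query(["A"], datasets=("d1", "d2")))
        assert [(a.start, a.end) for a in res.intervals] == [(9_000, 9_600)]
        assert res.intervals[0].provenance == {("d1", "A"), ("d2", "A")}

    def test_stats_consistent(self, simple):
        store, genes = simple
        engine = SearchEngine(store, genes)
        res = engine.run_search(query(["A"]))
        assert res.stats == {"region_count": 1, "total_span_bp": 400}

    def test_all_genes_unknown_raises(self, simple):
        from regusearch.genes import UnknownGenesError

        store, genes = simple
        engine = SearchEngine(store, genes)
        q = SearchQuery(
            build=BUILD, genes=("NOSUCH",), tissues=("A",),
            dataset_configs={"ds": DatasetConfig()},
        )
        with pytest.raises(UnknownGenesError):
            engine.run_search(q)

    def test_query_invariants(self):
        with pytest.raises(ValueError):
            SearchQuery(build=BUILD, genes=(), tissues=("A",), dataset_configs={"d": DatasetConfig()})
        with pytest.raises(ValueError):
            SearchQuery(build=BUILD, genes=("G",), tissues=("A",), dataset_configs={})
        with pytest.raises(ValueError):
            DatasetConfig(mode="sometimes")


class TestOutputs:
    def test_table_one_row_per_provenance_pair(self, simple):
        store, genes = simple
        store.add(make_track("ds2", "A", "promoter", BUILD, [gi("chr1", 9_100, 9_300)]))
        engine = SearchEngine(store, genes)
        res = engine.run_search(query(["A"], datasets=("ds", "ds2")))
        table = res.to_table()
        assert len(table) == 2  # one merged interval, two provenance pairs
        assert set(table["dataset"]) == {"ds", "ds2"}

    def test_empty_result_outputs_valid(self, simple, tmp_path):
        store, genes = simple
        engine = SearchEngine(store, genes)
        res = engine.run_search(query(["A"], up=10, down=10))
        assert res.intervals == []
        bed = tmp_path / "empty.bed"
        res.to_bed(bed, ucsc_track_header='track name="empty"')
        assert bed.read_text() == 'track name="empty"\n'
        assert res.ucsc_payload()["position"] == ""

    def test_position_string_is_one_based(self):
        from regusearch.intervals import AnnotatedInterval
        from regusearch.search import SearchResult

        res = SearchResult(
            intervals=[AnnotatedInterval(interval=GenomeInterval("chr8", 11_000, 20_000, BUILD))]
        )
        assert res.ucsc_payload()["position"] == "chr8:11001-20000"


# ---------------------------------------------------------------------------
# randomized stores: oracle equivalence and monotonicity


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("mode", ["any", "all"])
    def test_run_search_matches_literal_recheck(self, seed, mode):
        store, table, datasets, tissues = random_world(seed)
        up, down = 8_000, 3_000
        res = run_query(store, table, datasets, tissues[:3], mode, up, down)
        expected = [
            r
            for ds in datasets
            for r in brute_force_cis(
                store, table, ds, ["G0", "G1", "G2"], tissues[:3], up, down, mode, BUILD
            )
        ]
        got_mask = coverage_mask(res.intervals, 200_000, "chr1")
        exp_mask = np.zeros(200_000, dtype=bool)
        for _, s, e in expected:
            exp_mask[s:e] = True
        assert np.array_equal(got_mask, exp_mask)


class TestMonotonicity:
    @pytest.mark.parametrize("seed", [3, 4])
    def test_all_mode_result_contained_in_any_mode(self, seed):
        store, table, datasets, tissues = random_world(seed)
        r_any = run_query(store, table, datasets, tissues, "any", 5_000, 5_000)
        r_all = run_query(store, table, datasets, tissues, "all", 5_000, 5_000)
        m_any = coverage_mask(r_any.intervals, 200_000, "chr1")
        m_all = coverage_mask(r_all.intervals, 200_000, "chr1")
        assert not np.any(m_all & ~m_any)

    @pytest.mark.parametrize("seed", [5, 6])
    def test_adding_tissues_superset_under_any(self, seed):
        store, table, datasets, tissues = random_world(seed)
        small = run_query(store, table, datasets, tissues[:2], "any", 5_000, 5_000)
        big = run_query(store, table, datasets, tissues, "any", 5_000, 5_000)
        m_small = coverage_mask(small.intervals, 200_000, "chr1")
        m_big = coverage_mask(big.intervals, 200_000, "chr1")
        assert not np.any(m_small & ~m_big)

    @pytest.mark.parametrize("seed", [7, 8])
    def test_adding_tissue_with_track_subset_under_all(self, seed):
        store, table, datasets, tissues = random_world(seed)
        # ensure the added tissue has a track in every dataset
        added = tissues[3]
        for ds in datasets:
            if not store.tracks(dataset=ds, tissue=added):
                store.add(make_track(ds, added, "enhancer", BUILD, [gi("chr1", 0, 50)]))
        small = run_query(store, table, datasets, tissues[:3], "all", 5_000, 5_000)
        big = run_query(store, table, datasets, tissues[:4], "all", 5_000, 5_000)
        m_small = coverage_mask(small.intervals, 200_000, "chr1")
        m_big = coverage_mask(big.intervals, 200_000, "chr1")
        assert not np.any(m_big & ~m_small)

    @pytest.mark.parametrize("seed", [9, 10])
    def test_wider_windows_superset(self, seed):
        store, table, datasets, tissues = random_world(seed)
        narrow = run_query(store, table, datasets, tissues, "any", 1_000, 1_000)
        wide = run_query(store, table, datasets, tissues, "any", 20_000, 20_000)
        m_n = coverage_mask(narrow.intervals, 200_000, "chr1")
        m_w = coverage_mask(wide.intervals, 200_000, "chr1")
        assert not np.any(m_n & ~m_w)


class TestMirnaBranch:
    def test_mirna_loci_join_the_merged_result(self, fixture_set):
        fx = fixture_set
        engine = SearchEngine(
            fx.store, fx.gene_table, mirna_registry=fx.mirna_registry, mirna_loci=fx.mirna_loci
        )
        tissues = ("pancreas",)
        genes = tuple(fx.gene_table.genes)
        q = SearchQuery(
            build=BUILD,
            genes=genes,
            tissues=tissues,
            dataset_configs={d: DatasetConfig(upstream_bp=2_000, downstream_bp=2_000) for d in fx.store.datasets()},
            mirna_config=MirnaConfig(enabled=True),
        )
        res = engine.run_search(q)
        expected = brute_force_mirna(
            fx.mirna_registry, fx.mirna_loci, fx.store, list(genes), list(tissues), BUILD
        )
        assert expected, "fixture must plant at least one active miRNA"
        got_mask = coverage_mask(res.intervals, fx.spec.chrom_length, f"chrS{fx.spec.n_chroms}")
        for _, s, e in expected:
            assert got_mask[s:e].all()
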