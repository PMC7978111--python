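"""Track store registration and data-preparation transforms."""

import numpy as np
import pytest

from regusearch.intervals import GenomeInterval, total_span
from regusearch.tracks import (
    CagePeak,
    RegulatorClass,
    TrackStore,
    collapse_replicates,
    load_cage_table,
    make_track,
    promoters_from_cage,
    split_ccres,
    summarize_track,
)

from oracles import coverage_mask


def gi(chrom, start, end):
    return GenomeInterval(chrom, start, end, "hg38")


class TestRegistration:
    def test_collapse_on_ingest(self, tmp_path):
        bed = tmp_path / "t.bed"
        bed.write_text("chr1\t0\t100\nchr1\t50\t150\n")
        store = TrackStore()
        track = store.register_track("ENCODE_tfbs", "liver", "tfbs", "hg38", bed)
        assert [(iv.start, iv.end) for iv in track.intervals] == [(0, 150)]

    def test_available_tissues(self):
        store = TrackStore()
        store.add(make_track("d1", "liver", "tfbs", "hg38", [gi("chr1", 0, 10)]))
        store.add(make_track("d1", "brain", "tfbs", "hg38", [gi("chr1", 0, 10)]))
        store.add(make_track("d2", "liver", "promoter", "hg38", [gi("chr1", 0, 10)]))
        assert store.available_tissues() == ["brain", "liver"]
        assert store.available_tissues(cls="promoter") == ["liver"]
        assert store.available_tissues(dataset="d1") == ["brain", "liver"]

    def test_duplicate_key_rejected_unless_replace(self):
        store = TrackStore()
        t = make_track("d1", "liver", "tfbs", "hg38", [gi("chr1", 0, 10)])
        store.add(t)
        with pytest.raises(KeyError):
            store.add(t)
        store.add(t, replace_existing=True)

    def test_availability_grid(self):
        store = TrackStore()
        store.add(make_track("d1", "liver", "tfbs", "hg38", [gi("chr1", 0, 10)]))
        store.add(make_track("d2", "liver", "promoter", "hg38", [gi("chr1", 0, 10)]))
        grid = store.tissue_class_availability()
        assert grid["liver"] == {RegulatorClass.TFBS, RegulatorClass.PROMOTER}

    def test_manifest_round_trip(self, tmp_path):
        store = TrackStore()
        store.add(make_track("d1", "liver", "tfbs", "hg38", [gi("chr1", 5, 99)]))
        store.to_manifest(tmp_path / "m.yaml", tmp_path / "beds")
        back = TrackStore.from_manifest(tmp_path / "m.yaml")
        t = back.get("d1", "liver", "tfbs", "hg38")
        assert [(iv.start, iv.end) for iv in t.intervals] == [(5, 99)]


class TestCollapseReplicates:
    def test_overlapping_replicates_union(self):
        a = make_track("d", "liver", "tfbs", "hg38", [gi("chr1", 0, 100)])
        b = make_track("d", "liver", "tfbs", "hg38", [gi("chr1", 50, 150)])
        out = collapse_replicates([a, b])
        assert [(iv.start, iv.end) for iv in out.intervals] == [(0, 150)]

    def test_disjoint_replicates_sorted_concatenation(self):
        a = make_track("d", "liver", "tfbs", "hg38", [gi("chr1", 500, 600)])
        b = make_track("d", "liver", "tfbs", "hg38", [gi("chr1", 0, 100)])
        out = collapse_replicates([a, b])
        assert [(iv.start, iv.end) for iv in out.intervals] == [(0, 100), (500, 600)]

    def test_single_input_identity(self):
        a = make_track("d", "liver", "tfbs", "hg38", [gi("chr1", 0, 100)])
        assert collapse_replicates([a]) == a

    def test_mixed_keys_rejected(self):
        a = make_track("d", "liver", "tfbs", "hg38", [gi("chr1", 0, 10)])
        b = make_track("d", "brain", "tfbs", "hg38", [gi("chr1", 0, 10)])
        with pytest.raises(ValueError, match="mixed keys"):
            collapse_replicates([a, b])

    def test_span_subadditive_equality_iff_disjoint(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            tracks = []
            for _ in range(3):
                starts = rng.integers(0, 5000, size=10)
                widths = rng.integers(1, 200, size=10)
                tracks.append(
                    make_track(
                        "d", "liver", "tfbs", "hg38",
                        [gi("chr1", int(s), int(s + w)) for s, w in zip(starts, widths)],
                    )
                )
            merged = collapse_replicates(tracks)
            out_span = summarize_track(merged).total_span_bp
            in_spans = [summarize_track(t).total_span_bp for t in tracks]
            assert out_span <= sum(in_spans)
            pairwise_disjoint = all(
                not np.any(
                    coverage_mask(tracks[i].intervals, 6000, "chr1")
                    & coverage_mask(tracks[j].intervals, 6000, "chr1")
                )
                for i in range(3)
                for j in range(i + 1, 3)
            )
            assert (out_span == sum(in_spans)) == pairwise_disjoint


class TestPromotersFromCage:
    def peak(self, strand, start, end, tpm):
        return CagePeak(interval=gi("chr1", start, end), strand=strand, tpm=tpm)

    def test_plus_strand_extension(self):
        track = promoters_from_cage([self.peak("+", 1000, 1010, 12.0)])
        assert [(iv.start, iv.end) for iv in track.intervals] == [(800, 1010)]
        assert track.intervals[0].width == 10 + 200

    def test_below_threshold_dropped(self):
        track = promoters_from_cage([self.peak("+", 1000, 1010, 9.99)])
        assert track.intervals == ()

    def test_threshold_itself_survives_minus_strand(self):
        track = promoters_from_cage([self.peak("-", 1000, 1010, 10.0)])
        assert [(iv.start, iv.end) for iv in track.intervals] == [(1000, 1210)]

    def test_clamped_at_zero(self):
        track = promoters_from_cage([self.peak("+", 50, 60, 11.0)])
        assert [(iv.start, iv.end) for iv in track.intervals] == [(0, 60)]

    def test_genomic_left_mode(self):
        track = promoters_from_cage([self.peak("-", 1000, 1010, 11.0)], strand_aware=False)
        assert [(iv.start, iv.end) for iv in track.intervals] == [(800, 1010)]

    def test_per_base_oracle(self):
        rng = np.random.default_rng(17)
        peaks = [
            self.peak(
                "+" if rng.random() < 0.5 else "-",
                int(s),
                int(s) + int(w),
                float(rng.uniform(0, 20)),
            )
            for s, w in zip(rng.integers(210, 5000, 50), rng.integers(5, 60, 50))
        ]
        track = promoters_from_cage(peaks)
        expected = np.zeros(6000, dtype=bool)
        for p in peaks:
            if p.tpm < 10.0:
                continue
            if p.strand == "+":
                expected[max(0, p.interval.start - 200) : p.interval.end] = True
            else:
                expected[p.interval.start : p.interval.end + 200] = True
        assert np.array_equal(coverage_mask(track.intervals, 6000, "chr1"), expected)

    def test_cage_table_loader(self, tmp_path):
        p = tmp_path / "cage.tsv"
        p.write_text("chrom\tstart\tend\tstrand\ttpm\tsample\nchr1\t10\t20\t+\t11.5\tliver\n")
        peaks = load_cage_table(p)
        assert peaks[0].tpm == 11.5 and peaks[0].strand == "+"


class TestSplitCcres:
    def write(self, tmp_path, lines):
        p = tmp_path / "ccre.bed"
        p.write_text("".join(lines))
        return p

    def test_split_by_class_token(self, tmp_path):
        p = self.write(
            tmp_path,
            [
                "chr1\t0\t100\tpromoter-like\n",
                "chr1\t500\t600\tpromoter-like\n",
                "chr1\t1000\t1100\tenhancer-like\n",
            ],
        )
        tracks, skipped = split_ccres(p, dataset="SCREEN", tissue="liver")
        sizes = {t.cls: len(t.intervals) for t in tracks}
        assert sizes == {RegulatorClass.PROMOTER: 2, RegulatorClass.ENHANCER: 1}
        assert skipped == 0

    def test_unknown_token_skipped_and_counted(self, tmp_path):
        p = self.write(tmp_path, ["chr1\t0\t100\tpromoter-like\n", "chr1\t500\t600\tweird\n"])
        tracks, skipped = split_ccres(p, dataset="SCREEN", tissue="liver")
        assert skipped == 1
        assert sum(len(t.intervals) for t in tracks) + skipped == 2

    def test_all_unrecognized_errors(self, tmp_path):
        p = self.write(tmp_path, ["chr1\t0\t100\tmystery\n"])
        with pytest.raises(ValueError, match="recognizable"):
            split_ccres(p, dataset="SCREEN", tissue="liver")


class TestSummarize:
    def test_arithmetic(self):
        t = make_track("d", "x", "tfbs", "hg38", [gi("chr1", 0, 100), gi("chr1", 200, 250)])
        s = summarize_track(t)
        assert (s.region_count, s.mean_size_bp, s.total_span_bp) == (2, 75.0, 150)

    def test_single_base(self):
        t = make_track("d", "x", "tfbs", "hg38", [gi("chr1", 5, 6)])
        s = summarize_track(t)
        assert (s.region_count, s.mean_size_bp, s.total_span_bp) == (1, 1.0, 1)

    def test_bookended_pair_collapses_to_one(self):
        t = make_track("d", "x", "tfbs", "hg38", [gi("chr1", 0, 10), gi("chr1", 10, 20)])
        assert summarize_track(t).region_count == 1
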