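"""Write -> reopen -> query: round trips, zoom correctness, determinism,
index efficiency, endianness, and corrupt-file handling."""

import math
from io import BytesIO

import numpy as np
import pytest

from bbikit import (
    BbiFormatError,
    ChromSizes,
    SignalInterval,
    ValidationError,
    WrongFileKindError,
    bed_schema,
    merge_summaries,
    open_bbi,
    summarize_intervals,
    write_bigbed,
    write_bigwig,
)
from bbikit.fixtures import (
    TrackSpec,
    depth_oracle,
    gen_corrupt_bbi,
    gen_signal_track,
)
from bbikit.read import _require_bigbed, _require_bigwig
from bbikit.write import WriteOptions, parallel_section_encode, plan_zoom_levels

from conftest import write_feats, write_track
from helpers import bin_edges, oracle_summary, swap_uncompressed_bigwig


def as_f32(ivs):
    return [(iv.chrom, iv.start, iv.end, np.float32(iv.value)) for iv in ivs]


class TestBigWigRoundTrip:
    def test_small_explicit_track(self):
        chroms = ChromSizes([("chr1", 1000)])
        ivs = [SignalInterval("chr1", 0, 10, 1.5), SignalInterval("chr1", 10, 20, 2.5),
               SignalInterval("chr1", 500, 900, -3.25)]
        f = write_track(ivs, chroms)
        assert f.kind == "bigwig"
        assert f.metadata.version == 4
        assert list(f.intervals("chr1")) == ivs
        whole = summarize_intervals(ivs, "chr1", 0, 1000)
        assert f.metadata.total_summary == whole

    def test_random_track_identity(self, track, small_genome, bigwig):
        intervals, _ = track
        assert as_f32(bigwig.iter_all()) == as_f32(intervals)
        assert bigwig.chroms() == dict(small_genome.items())

    def test_region_query_matches_linear_scan(self, track, bigwig):
        intervals, _ = track
        rng = np.random.default_rng(2)
        for _ in range(30):
            chrom = f"chr{rng.integers(1, 3)}"
            a, b = sorted(rng.integers(0, 3000, 2).tolist())
            if a == b:
                continue
            got = list(bigwig.intervals(chrom, a, b))
            expect = [iv for iv in intervals if iv.chrom == chrom and iv.start < b and iv.end > a]
            assert as_f32(got) == as_f32(expect)

    def test_empty_stream_rejected(self, small_genome):
        with pytest.raises(ValidationError, match="no data"):
            write_bigwig(iter([]), small_genome, BytesIO())

    def test_unsorted_rejected(self, small_genome):
        bad = [SignalInterval("chr1", 100, 200, 1.0), SignalInterval("chr1", 50, 60, 1.0)]
        with pytest.raises(ValidationError, match="out of order"):
            write_bigwig(iter(bad), small_genome, BytesIO())

    def test_overlap_rejected_names_pair(self, small_genome):
        bad = [SignalInterval("chr1", 0, 100, 1.0), SignalInterval("chr1", 50, 150, 2.0)]
        with pytest.raises(ValidationError, match=r"chr1:50-150 overlaps .*chr1:0-100"):
            write_bigwig(iter(bad), small_genome, BytesIO())

    def test_beyond_chrom_end_rejected_unless_clipped(self, small_genome):
        ivs = [SignalInterval("chrM", 700, 900, 1.0)]
        with pytest.raises(ValidationError, match="past chromosome end"):
            write_bigwig(iter(ivs), small_genome, BytesIO())
        f = write_track(ivs, small_genome, WriteOptions(clip=True))
        assert list(f.intervals("chrM")) == [SignalInterval("chrM", 700, 800, 1.0)]

    def test_unknown_chrom_rejected(self, small_genome):
        with pytest.raises(ValidationError, match="unknown chromosome"):
            write_bigwig(iter([SignalInterval("chrZ", 0, 10, 1.0)]), small_genome, BytesIO())

    def test_single_pass_input_consumption(self, track, small_genome):
        """The writer never rewinds its input: positions are visited once, forward."""
        intervals, _ = track
        pulls = []

        def instrumented():
            for i, iv in enumerate(intervals):
                pulls.append(i)
                yield iv

        write_bigwig(instrumented(), small_genome, BytesIO())
        assert pulls == sorted(pulls) and len(pulls) == len(intervals)


class TestValuesAndStats:
    def test_values_basic_and_past_end(self):
        chroms = ChromSizes([("chr1", 12)])
        f = write_track([SignalInterval("chr1", 0, 10, 2.0)], chroms)
        np.testing.assert_array_equal(f.values("chr1", 0, 10), np.full(10, 2.0))
        got = f.values("chr1", 5, 12)
        np.testing.assert_array_equal(got[:5], np.full(5, 2.0))
        assert np.isnan(got[5:]).all()

    def test_values_binned_mean(self):
        chroms = ChromSizes([("chr1", 100)])
        ivs = [SignalInterval("chr1", 0, 10, 1.0), SignalInterval("chr1", 10, 20, 3.0)]
        f = write_track(ivs, chroms)
        np.testing.assert_array_equal(f.values("chr1", 0, 20, bins=2), [1.0, 3.0])

    def test_values_match_intervals_everywhere(self, track, bigwig):
        """Dense values and interval queries are mutually consistent."""
        _, oracle = track
        for chrom, arr in oracle.items():
            np.testing.assert_array_equal(bigwig.values(chrom), arr)

    def test_stats_exact_against_oracle(self, track, bigwig):
        _, oracle = track
        rng = np.random.default_rng(3)
        for chrom, arr in oracle.items():
            for bins in (1, 3, 10):
                a, b = sorted(rng.integers(0, len(arr), 2).tolist())
                if b - a < bins:
                    continue
                means = bigwig.stats(chrom, a, b, "mean", bins=bins, exact=True)
                covs = bigwig.stats(chrom, a, b, "coverage", bins=bins, exact=True)
                edges = bin_edges(a, b, bins)
                for i, (lo, hi) in enumerate(zip(edges, edges[1:])):
                    n, mn, mx, sm, _ = oracle_summary(arr, lo, hi)
                    assert covs[i] == pytest.approx(n / (hi - lo))
                    if n:
                        assert means[i] == pytest.approx(sm / n, rel=1e-6)
                    else:
                        assert math.isnan(means[i])

    def test_stats_simple_examples(self):
        chroms = ChromSizes([("chr1", 100)])
        ivs = [SignalInterval("chr1", 0, 10, 1.0), SignalInterval("chr1", 10, 20, 3.0)]
        f = write_track(ivs, chroms)
        assert f.stats("chr1", 0, 20, "mean") == [pytest.approx(2.0)]
        assert f.stats("chr1", 0, 100, "coverage") == [pytest.approx(0.2)]
        assert f.stats("chr1", 0, 20, "min") == [1.0]
        assert f.stats("chr1", 0, 20, "max") == [3.0]
        assert f.stats("chr1", 0, 20, "sum") == [pytest.approx(40.0)]

    def test_approximate_stats_error_bound(self, small_genome):
        """Zoom-backed means deviate by at most max|value| * (reduction / bin width)."""
        spec = TrackSpec(seed=42, chroms=small_genome, interval_count=400,
                         length_range=(1, 20), value_range=(0.0, 8.0), gap_probability=0.2)
        intervals, oracle = gen_signal_track(spec)
        f = write_track(intervals, small_genome)
        levels = [z.reduction_level for z in f.metadata.zoom_levels]
        assert levels, "fixture must produce zoom levels"
        for chrom, arr in oracle.items():
            width = len(arr) // 4
            usable = [l for l in levels if l <= width / 2]
            if not usable:
                continue
            level = max(usable)
            exact = f.stats(chrom, 0, width * 4, "mean", bins=4, exact=True)
            approx = f.stats(chrom, 0, width * 4, "mean", bins=4, exact=False)
            bound = 8.0 * level / width + 1e-9
            for e, a in zip(exact, approx):
                if not (math.isnan(e) or math.isnan(a)):
                    assert abs(e - a) <= bound

    def test_zero_length_bin_rejected(self, bigwig):
        with pytest.raises(ValidationError, match="bin"):
            bigwig.stats("chr1", 0, 3, bins=5)

    def test_kind_errors(self, bigwig, bigbed):
        with pytest.raises(WrongFileKindError):
            _require_bigwig(bigbed)
        with pytest.raises(WrongFileKindError):
            _require_bigbed(bigwig)


class TestZoom:
    def test_zoom_records_match_raw_aggregation(self, track, small_genome, bigwig):
        """Every zoom bin's stats equal a fresh aggregation of the raw data."""
        intervals, _ = track
        for z in bigwig.metadata.zoom_levels:
            for info in bigwig.metadata.chrom_table:
                recs = bigwig.zoom_query(info.name, 0, info.length, z.reduction_level)
                for rec in recs:
                    assert rec.start % z.reduction_level == 0
                    assert rec.end - rec.start <= z.reduction_level
                    raw = summarize_intervals(intervals, info.name, rec.start, rec.end)
                    assert rec.stats.valid_count == raw.valid_count
                    assert rec.stats.min_val == pytest.approx(raw.min_val, rel=1e-6)
                    assert rec.stats.max_val == pytest.approx(raw.max_val, rel=1e-6)
                    assert rec.stats.sum == pytest.approx(raw.sum, rel=1e-5)
                    assert rec.stats.sum_squares == pytest.approx(raw.sum_squares, rel=1e-5)

    def test_coarsest_level_folds_to_total_summary(self, bigwig):
        coarsest = bigwig.metadata.zoom_levels[-1].reduction_level
        folded = None
        for info in bigwig.metadata.chrom_table:
            for rec in bigwig.zoom_query(info.name, 0, info.length, coarsest):
                folded = rec.stats if folded is None else merge_summaries(folded, rec.stats)
        total = bigwig.metadata.total_summary
        assert folded.valid_count == total.valid_count
        assert folded.sum == pytest.approx(total.sum, rel=1e-6)
        assert folded.sum_squares == pytest.approx(total.sum_squares, rel=1e-6)

    def test_absent_level_lists_available(self, bigwig):
        with pytest.raises(ValidationError, match="available"):
            bigwig.zoom_query("chr1", 0, 100, reduction_level=7)

    def test_query_before_any_data_is_empty(self, small_genome):
        ivs = [SignalInterval("chr1", 4000, 4500, 1.0)]
        f = write_track(ivs, small_genome, WriteOptions(zoom_levels=[100]))
        assert f.zoom_query("chr1", 0, 1000, reduction_level=100) == []


class TestZoomPlanning:
    def test_auto_rule_long_genome(self):
        # 1000 * 4^9 >= 10^8, so the ladder stops after nine levels
        chroms = ChromSizes([("chr1", 10**8)])
        levels = plan_zoom_levels(1000, 100.0, chroms)
        assert levels == [1000 * 4**i for i in range(9)]
        # the ten-level cap binds on an even longer genome
        chroms2 = ChromSizes([("chr1", 2**32 - 1)])
        assert plan_zoom_levels(1000, 100.0, chroms2) == [1000 * 4**i for i in range(10)]

    def test_auto_rule_stops_at_longest_chrom(self):
        chroms = ChromSizes([("c", 500)])
        assert plan_zoom_levels(50, 1.0, chroms) == [10, 40, 160]

    def test_explicit_override(self):
        chroms = ChromSizes([("c", 10**6)])
        opts = WriteOptions(zoom_levels=[100])
        assert plan_zoom_levels(5000, 1.0, chroms, opts) == [100]

    def test_no_levels_when_first_exceeds_genome(self):
        chroms = ChromSizes([("c", 50)])
        assert plan_zoom_levels(3, 10.0, chroms) == []


class TestDeterminism:
    def test_temp_files_and_threads_do_not_change_bytes(self, small_genome):
        spec = TrackSpec(seed=17, chroms=small_genome, interval_count=500)
        intervals, _ = gen_signal_track(spec)
        outputs = []
        for temp in (True, False):
            for threads in (1, 4):
                buf = BytesIO()
                write_bigwig(
                    iter(intervals), small_genome, buf,
                    WriteOptions(use_temp_files=temp, threads=threads),
                )
                outputs.append(buf.getvalue())
        assert all(o == outputs[0] for o in outputs[1:])

    def test_parallel_section_encode_orders_like_serial(self):
        rng = np.random.default_rng(6)
        payloads = [rng.bytes(rng.integers(10, 2000)) for _ in range(1000)]
        serial = list(parallel_section_encode(iter(payloads), 1, True))
        threaded = list(parallel_section_encode(iter(payloads), 4, True))
        assert serial == threaded
        single = list(parallel_section_encode(iter(payloads[:1]), 8, True))
        assert single == serial[:1]


class TestIndexEfficiency:
    def test_small_query_touches_few_sections(self):
        """A 1 kb query on a large multi-chromosome file decompresses <5% of sections."""
        chroms = ChromSizes([(f"chr{i}", 1_000_000) for i in range(1, 11)])
        spec = TrackSpec(seed=8, chroms=chroms, interval_count=100_000,
                         length_range=(5, 20), gap_probability=0.1)
        intervals, _ = gen_signal_track(spec)
        buf = BytesIO()
        write_bigwig(iter(intervals), chroms, buf)
        f = open_bbi(buf)
        total_sections = -(-100_000 // 1024) + 10  # upper bound incl. per-chrom splits
        f.sections_decoded = 0
        list(f.intervals("chr5", 500_000, 501_000))
        assert f.sections_decoded > 0
        assert f.sections_decoded / total_sections < 0.05


class TestEndianness:
    def test_byte_swapped_file_reads_identically(self, small_genome):
        spec = TrackSpec(seed=19, chroms=small_genome, interval_count=120)
        intervals, _ = gen_signal_track(spec)
        buf = BytesIO()
        write_bigwig(iter(intervals), small_genome, buf, WriteOptions(compress=False))
        little = buf.getvalue()
        big = swap_uncompressed_bigwig(little)
        assert big != little
        f = open_bbi(BytesIO(big))
        assert as_f32(f.iter_all()) == as_f32(intervals)
        ref = open_bbi(BytesIO(little))
        assert f.metadata.total_summary == ref.metadata.total_summary
        lvl = f.metadata.zoom_levels[0].reduction_level
        assert f.zoom_query("chr1", reduction_level=lvl) == ref.zoom_query(
            "chr1", reduction_level=lvl
        )

    def test_random_bytes_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(BbiFormatError, match="not a BBI file"):
            open_bbi(BytesIO(rng.bytes(64)))


class TestCorruptFiles:
    @pytest.fixture
    def valid_bytes(self, track, small_genome):
        intervals, _ = track
        buf = BytesIO()
        write_bigwig(iter(intervals), small_genome, buf)
        return buf.getvalue()

    def test_bad_magic(self, valid_bytes):
        with pytest.raises(BbiFormatError, match="not a BBI file"):
            open_bbi(BytesIO(gen_corrupt_bbi(valid_bytes, "bad_magic")))

    def test_truncated(self, valid_bytes):
        data = gen_corrupt_bbi(valid_bytes, "truncated")
        with pytest.raises(BbiFormatError):
            f = open_bbi(BytesIO(data))
            list(f.iter_all())

    def test_bad_section_size(self, valid_bytes):
        data = gen_corrupt_bbi(valid_bytes, "bad_section_size")
        f = open_bbi(BytesIO(data))
        with pytest.raises(BbiFormatError, match="buffer size"):
            list(f.iter_all())

    def test_bad_node_magic(self, valid_bytes):
        data = gen_corrupt_bbi(valid_bytes, "bad_node_magic")
        f = open_bbi(BytesIO(data))
        with pytest.raises(BbiFormatError, match="R-tree magic"):
            list(f.iter_all())


class TestBigBed:
    def test_overlapping_records_round_trip(self, features, small_genome, bigbed):
        assert list(bigbed.iter_all()) == features
        assert bigbed.metadata.field_count == 6
        assert bigbed.metadata.defined_field_count == 6

    def test_region_query_no_duplicates(self, features, bigbed):
        rng = np.random.default_rng(13)
        for _ in range(25):
            chrom = f"chr{rng.integers(1, 3)}"
            a, b = sorted(rng.integers(0, 3000, 2).tolist())
            if a == b:
                continue
            got = list(bigbed.records(chrom, a, b))
            expect = [r for r in features if r.chrom == chrom and r.start < b and r.end > a]
            assert got == expect  # equality implies no duplicates and full recall

    def test_depth_zoom_matches_oracle(self, features, small_genome, bigbed):
        """Zoom stats summarize per-base coverage depth."""
        depth = depth_oracle(features, small_genome)
        for z in bigbed.metadata.zoom_levels:
            for info in bigbed.metadata.chrom_table:
                for rec in bigbed.zoom_query(info.name, 0, info.length, z.reduction_level):
                    arr = depth[info.name][rec.start : rec.end]
                    covered = arr[arr > 0]
                    assert rec.stats.valid_count == covered.size
                    if covered.size:
                        assert rec.stats.min_val == covered.min()
                        assert rec.stats.max_val == covered.max()
                        assert rec.stats.sum == pytest.approx(covered.sum(), rel=1e-6)

    def test_embedded_autosql_round_trip(self, features, small_genome):
        schema = bed_schema(6)
        f = write_feats(features, small_genome, autosql=schema)
        assert f.autosql() == schema

    def test_schema_field_count_mismatch(self, features, small_genome):
        with pytest.raises(ValidationError, match="fields"):
            write_feats(features, small_genome, autosql=bed_schema(4))

    def test_out_of_order_rejected(self, small_genome):
        from bbikit import BedRecord

        bad = [BedRecord("chr1", 100, 200), BedRecord("chr1", 50, 60)]
        with pytest.raises(ValidationError, match="out of order"):
            write_bigbed(iter(bad), small_genome, BytesIO())

    def test_total_summary_is_depth_summary(self, features, small_genome, bigbed):
        depth = depth_oracle(features, small_genome)
        allv = np.concatenate([a[a > 0] for a in depth.values()])
        ts = bigbed.metadata.total_summary
        assert ts.valid_count == allv.size
        assert ts.sum == pytest.approx(allv.sum())
        assert ts.min_val == allv.min() and ts.max_val == allv.max()


class TestStructuralValidity:
    def test_metadata_consistency_over_many_seeds(self):
        for seed in range(5):
            chroms = ChromSizes([("chr1", 8000), ("chr2", 2000)])
            intervals, _ = gen_signal_track(
                TrackSpec(seed=seed, chroms=chroms, interval_count=150)
            )
            buf = BytesIO()
            md = write_bigwig(iter(intervals), chroms, buf)
            f = open_bbi(buf)
            reds = [z.reduction_level for z in f.metadata.zoom_levels]
            assert reds == sorted(reds)
            assert f.metadata.zoom_levels == md.zoom_levels
            # total summary equals the fold of per-interval summaries
            fold = summarize_intervals(intervals, "chr1", 0, 8000).merge(
                summarize_intervals(intervals, "chr2", 0, 2000)
            )
            ts = f.metadata.total_summary
            assert (ts.valid_count, ts.min_val, ts.max_val) == (
                fold.valid_count, fold.min_val, fold.max_val,
            )
            assert ts.sum == pytest.approx(fold.sum, rel=1e-9)
            assert ts.sum_squares == pytest.approx(fold.sum_squares, rel=1e-9)
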