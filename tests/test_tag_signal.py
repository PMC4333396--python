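import numpy as np
import pytest

from chromphi.genome_model import ChromTable, GenomicInterval, tile_genome
from chromphi.tag_signal import (
    SamplePair,
    SignalTrack,
    count_in_windows,
    load_tags,
    region_si,
    replicate_correlation,
    rpkm,
    signal_intensity,
    sliding_track,
)

from conftest import make_tagset


def brute_force_counts(rows, grid):
    """Independent per-tag, per-window containment scan."""
    out = []
    for chrom in grid.chrom_table.chroms:
        for s in grid.starts.get(chrom, []):
            out.append(
                sum(1 for c, p, _ in rows if c == chrom and s <= p < s + grid.width)
            )
    return np.array(out)


class TestLoadTags:
    def test_dedup_flag(self, tmp_path, chrom_table):
        p = tmp_path / "tags.bed"
        p.write_text(
            "chr1\t100\t136\tt\t0\t+\n"
            "chr1\t100\t136\tt\t0\t+\n"
            "chr1\t200\t236\tt\t0\t+\n"
        )
        assert load_tags(p, chrom_table, dedup=True).n_unique == 2
        assert load_tags(p, chrom_table, dedup=False).n_unique == 3

    def test_minus_strand_pos5_is_end_minus_one(self, tmp_path, chrom_table):
        p = tmp_path / "tags.bed"
        p.write_text("chr1\t100\t136\tt\t0\t-\n")
        tags = load_tags(p, chrom_table)
        assert tags.pos("chr1").tolist() == [135]

    def test_unknown_chromosome_reports_row(self, tmp_path, chrom_table):
        p = tmp_path / "tags.bed"
        p.write_text("chr1\t10\t46\tt\t0\t+\nchrX\t10\t46\tt\t0\t+\n")
        with pytest.raises(ValueError, match="row 2"):
            load_tags(p, chrom_table)

    def test_empty_file_warns(self, tmp_path, chrom_table, caplog):
        p = tmp_path / "tags.bed"
        p.write_text("")
        with caplog.at_level("WARNING"):
            tags = load_tags(p, chrom_table)
        assert tags.n_unique == 0

    def test_bed3_defaults_to_plus(self, tmp_path, chrom_table):
        p = tmp_path / "tags.bed"
        p.write_text("chr1\t100\t136\n")
        assert load_tags(p, chrom_table).pos("chr1").tolist() == [100]


class TestCounting:
    def test_non_overlapping_assignment(self, chrom_table):
        tags = make_tagset(chrom_table, [("chr1", 50, "+"), ("chr1", 250, "+")])
        grid = tile_genome(chrom_table, 200, 200)
        counts = count_in_windows(tags, grid)
        assert counts[:3].tolist() == [1, 1, 0]
        assert counts.sum() == 2

    def test_overlapping_windows_count_tag_twice(self, chrom_table):
        tags = make_tagset(chrom_table, [("chr1", 1_500, "+")])
        grid = tile_genome(chrom_table, 2_000, 1_000)
        counts = count_in_windows(tags, grid)
        assert counts.tolist() == brute_force_counts([("chr1", 1_500, "+")], grid).tolist()
        hits = {int(s) for s, c in zip(grid.starts["chr1"], counts) if c}
        assert hits == {0, 1_000}  # windows [0,2000) and [1000,3000)

    def test_empty_tagset_gives_zeros(self, chrom_table):
        tags = make_tagset(chrom_table, [])
        grid = tile_genome(chrom_table, 200, 200)
        assert count_in_windows(tags, grid).sum() == 0

    def test_matches_brute_force_on_random_tags(self, chrom_table):
        rng = np.random.default_rng(11)
        rows = [
            ("chr1" if rng.integers(2) else "chr2",
             int(rng.integers(0, 5_000)), "+" if rng.integers(2) else "-")
            for _ in range(80)
        ]
        tags = make_tagset(chrom_table, rows, dedup=False)
        for width, step in [(200, 200), (1_000, 500), (2_000, 1_000)]:
            grid = tile_genome(chrom_table, width, step)
            assert count_in_windows(tags, grid).tolist() == \
                brute_force_counts(rows, grid).tolist()

    def test_total_count_conservation(self, chrom_table):
        """Tags in full windows + tags in dropped terminal stubs = n_unique."""
        rng = np.random.default_rng(3)
        rows = [("chr2", int(p), "+") for p in rng.choice(5_000, 60, replace=False)]
        tags = make_tagset(chrom_table, rows)
        grid = tile_genome(chrom_table, 300, 300)  # 5000 % 300 != 0 -> stub
        covered = count_in_windows(tags, grid).sum()
        stub_start = (5_000 // 300) * 300
        in_stub = sum(1 for _, p, _ in rows if p >= stub_start)
        assert covered + in_stub == tags.n_unique


class TestRpkm:
    @pytest.mark.parametrize(
        "count,width,n_total,expected",
        [(10, 2_000, 1_000_000, 5.0), (0, 2_000, 1_000_000, 0.0),
         (3, 200, 2_000_000, 7.5)],
    )
    def test_values(self, count, width, n_total, expected):
        assert rpkm([count], [width], n_total)[0] == pytest.approx(expected)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            rpkm([1], [200], 0)

    def test_scale_invariance(self):
        """Doubling every count and the library size leaves RPKM unchanged."""
        counts = np.array([3, 7, 0, 12])
        a = rpkm(counts, np.full(4, 500), 1_000_000)
        b = rpkm(2 * counts, np.full(4, 500), 2_000_000)
        assert np.allclose(a, b)


def _pair(chrom_table, ip_rows, input_rows):
    ip = make_tagset(chrom_table, ip_rows, sample_id="ip", mark="H3K4me3")
    ctrl = make_tagset(chrom_table, input_rows, sample_id="in", mark="input")
    return SamplePair(ip=ip, input=ctrl)


class TestSignalIntensity:
    def test_identical_samples_give_zero(self, chrom_table):
        rows = [("chr1", int(p), "+") for p in range(0, 5_000, 97)]
        pair = _pair(chrom_table, rows, rows)
        track = signal_intensity(pair, tile_genome(chrom_table, 200, 200))
        assert np.allclose(track.values, 0)

    def test_antisymmetry(self, chrom_table):
        rng = np.random.default_rng(5)
        a = [("chr1", int(p), "+") for p in rng.choice(9_000, 40, replace=False)]
        b = [("chr1", int(p), "-") for p in rng.choice(9_000, 60, replace=False)]
        grid = tile_genome(chrom_table, 500, 500)
        fwd = signal_intensity(_pair(chrom_table, a, b), grid).values
        # reversed roles: relabel marks so the pair validates
        ip = make_tagset(chrom_table, b, sample_id="ip", mark="H3K4me3")
        ctrl = make_tagset(chrom_table, a, sample_id="in", mark="input")
        rev = signal_intensity(SamplePair(ip=ip, input=ctrl), grid).values
        assert np.allclose(fwd, -rev)

    def test_pair_validation(self, chrom_table):
        ip = make_tagset(chrom_table, [("chr1", 1, "+")], mark="H3K4me3")
        not_input = make_tagset(chrom_table, [("chr1", 2, "+")], mark="H3.3")
        with pytest.raises(ValueError):
            SamplePair(ip=ip, input=not_input)


class TestRegionSi:
    def test_direct_arithmetic(self):
        """40 IP vs 10 input tags in a 4 kb region at 1e6 depth: SI = 10 - 2.5."""
        ct = ChromTable([("chr1", 1_000_000)])
        ip_rows = [("chr1", 2_000 + 100 * i, "+") for i in range(40)]
        in_rows = [("chr1", 2_000 + 400 * i, "+") for i in range(10)]
        # region_si normalizes by n_unique; set the nominal library sizes directly
        ip = make_tagset(ct, ip_rows, mark="H3K4me3")
        ctrl = make_tagset(ct, in_rows, mark="input")
        ip.n_unique = 1_000_000
        ctrl.n_unique = 1_000_000
        si = region_si(SamplePair(ip=ip, input=ctrl),
                       GenomicInterval("chr1", 2_000, 6_000))
        assert si == pytest.approx(7.5)

    def test_consistent_with_tiled_si(self, chrom_table):
        """region_si over a grid window equals signal_intensity for that window."""
        rng = np.random.default_rng(9)
        ip_rows = [("chr1", int(p), "+") for p in rng.choice(10_000, 50, replace=False)]
        in_rows = [("chr1", int(p), "+") for p in rng.choice(10_000, 30, replace=False)]
        pair = _pair(chrom_table, ip_rows, in_rows)
        grid = tile_genome(chrom_table, 4_000, 4_000)
        track = signal_intensity(pair, grid)
        si = region_si(pair, GenomicInterval("chr1", 4_000, 8_000))
        assert si == pytest.approx(track.values[1])

    def test_no_tags_gives_zero(self, chrom_table):
        pair = _pair(chrom_table, [("chr1", 9_999, "+")], [("chr1", 9_998, "+")])
        assert region_si(pair, GenomicInterval("chr1", 0, 1_000)) == 0.0


class TestSlidingTrack:
    def test_single_cluster_elevates_exactly_two_windows(self, chrom_table):
        ip_rows = [("chr1", 3_000 + 2 * i, "+") for i in range(50)]
        in_rows = [("chr1", int(p), "+") for p in range(0, 10_000, 100)]
        pair = _pair(chrom_table, ip_rows, in_rows)
        track = sliding_track(pair, chrom_table, width=2_000, step=1_000)
        starts = track.grid.starts["chr1"]
        vals = track.values[track.grid.chrom_slices()["chr1"]]
        elevated = {int(s) for s, v in zip(starts, vals) if v > vals.max() / 2}
        assert elevated == {2_000, 3_000}

    def test_step_equals_width_reduces_to_tiled_si(self, chrom_table):
        rng = np.random.default_rng(17)
        ip_rows = [("chr1", int(p), "+") for p in rng.choice(10_000, 70, replace=False)]
        in_rows = [("chr1", int(p), "+") for p in rng.choice(10_000, 70, replace=False)]
        pair = _pair(chrom_table, ip_rows, in_rows)
        track = sliding_track(pair, chrom_table, width=500, step=500)
        tiled = signal_intensity(pair, tile_genome(chrom_table, 500, 500))
        assert np.allclose(track.values, tiled.values)

    def test_empty_ip_gives_nonpositive_si(self, chrom_table):
        in_rows = [("chr1", int(p), "+") for p in range(0, 10_000, 50)]
        pair = _pair(chrom_table, [("chr2", 4_999, "+")], in_rows)
        track = sliding_track(pair, chrom_table)
        sl = track.grid.chrom_slices()["chr1"]
        assert (track.values[sl] <= 0).all()


class TestReplicateCorrelation:
    def _track(self, chrom_table, values):
        grid = tile_genome(chrom_table, 2_000, 2_000)
        return SignalTrack(grid, "H3.3", f"s{id(values) % 97}", values, "si")

    def test_self_correlation_is_one(self, chrom_table):
        rng = np.random.default_rng(2)
        v = rng.normal(size=tile_genome(chrom_table, 2_000, 2_000).n_windows)
        df, mean = replicate_correlation([self._track(chrom_table, v),
                                          self._track(chrom_table, v.copy())])
        assert mean == pytest.approx(1.0)

    def test_negation_gives_minus_one(self, chrom_table):
        rng = np.random.default_rng(2)
        v = rng.normal(size=tile_genome(chrom_table, 2_000, 2_000).n_windows)
        _, mean = replicate_correlation([self._track(chrom_table, v),
                                         self._track(chrom_table, -v)])
        assert mean == pytest.approx(-1.0)

    def test_constant_track_rejected(self, chrom_table):
        n = tile_genome(chrom_table, 2_000, 2_000).n_windows
        with pytest.raises(ValueError):
            replicate_correlation([
                self._track(chrom_table, np.zeros(n)),
                self._track(chrom_table, np.arange(n, dtype=float)),
            ])

    def test_mean_is_upper_triangle_average(self, chrom_table):
        rng = np.random.default_rng(4)
        n = tile_genome(chrom_table, 2_000, 2_000).n_windows
        tracks = [self._track(chrom_table, rng.normal(size=n)) for _ in range(3)]
        df, mean = replicate_correlation(tracks)
        m = df.to_numpy()
        assert mean == pytest.approx((m[0, 1] + m[0, 2] + m[1, 2]) / 3)
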