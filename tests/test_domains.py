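import math

import numpy as np
import pytest

from epispread.domains import (
    PRESET_THRESHOLDS,
    CategoryBounds,
    CategoryThresholds,
    DiffPlotRecord,
    RegionCounts,
    aggregate_profile,
    categorize,
    diff_plot_coordinates,
    load_thresholds,
    proportion_in_features,
    region_scaled_profile,
    signal_matrix_kmeans,
    spread_correlation,
    top_percent_score,
)
from epispread.genome import (
    GenomeDescription,
    GenomicInterval,
    TagCollection,
    make_bins,
)
from epispread.normalize import BinTrack


def _track(partition, values, total=None):
    return BinTrack(partition, values, total_reads=total, is_counts=False)


@pytest.fixture
def part100():
    return make_bins(GenomeDescription((("chrA", 100_000),)), 1000)


class TestTopPercentScore:
    def test_top_bin_of_hundred(self, part100):
        chip = _track(part100, np.arange(1.0, 101.0))
        inp = _track(part100, np.zeros(100))
        assert top_percent_score(chip, inp) == 100.0

    def test_constant_difference(self, part100):
        chip = _track(part100, np.full(100, 7.5))
        inp = _track(part100, np.full(100, 2.5))
        assert top_percent_score(chip, inp) == pytest.approx(5.0)

    @pytest.mark.parametrize("pct", [0.5, 1.0, 10.0])
    def test_matches_full_sort_oracle(self, pct):
        rng = np.random.default_rng(17)
        part = make_bins(GenomeDescription((("chrA", 10_000_000),)), 1000)
        chip = _track(part, rng.normal(size=10_000))
        inp = _track(part, rng.normal(size=10_000))
        diff = sorted(chip.values - inp.values, reverse=True)
        k = math.ceil(pct / 100 * len(diff))
        assert top_percent_score(chip, inp, pct) == pytest.approx(
            float(np.mean(diff[:k]))
        )

    def test_out_of_range_pct_rejected(self, part100):
        chip = _track(part100, np.zeros(100))
        with pytest.raises(ValueError):
            top_percent_score(chip, chip, pct=0.0)
        with pytest.raises(ValueError):
            top_percent_score(chip, chip, pct=101.0)


class TestProportionInFeatures:
    def test_whole_genome_is_one(self):
        tags = TagCollection({"chrA": [1, 2, 3, 500]})
        assert proportion_in_features(tags, [GenomicInterval("chrA", 0, 1000)]) == 1.0

    def test_empty_features_zero(self):
        tags = TagCollection({"chrA": [1]})
        assert proportion_in_features(tags, []) == 0.0

    def test_overlapping_features_not_double_counted(self):
        tags = TagCollection({"chrA": [10, 20, 90]})
        feats = [GenomicInterval("chrA", 0, 50), GenomicInterval("chrA", 25, 60)]
        assert proportion_in_features(tags, feats) == pytest.approx(2 / 3)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_membership_oracle(self, seed):
        rng = np.random.default_rng(seed)
        positions = sorted(rng.integers(0, 100_000, 2_000).tolist())
        tags = TagCollection({"chrA": positions})
        feats = [
            GenomicInterval("chrA", int(s), int(s + rng.integers(100, 3_000)))
            for s in rng.integers(0, 95_000, 40)
        ]
        n_in = sum(
            1
            for p in positions
            if any(f.start <= p < f.end for f in feats)
        )
        assert proportion_in_features(tags, feats) == pytest.approx(
            n_in / len(positions)
        )

    def test_no_reads_rejected(self):
        with pytest.raises(ValueError):
            proportion_in_features(
                TagCollection({}), [GenomicInterval("chrA", 0, 10)]
            )


class TestDiffPlotCoordinates:
    def _regions(self, n):
        return [GenomicInterval("chrA", 1000 * i, 1000 * i + 500) for i in range(n)]

    def test_wt_four_fold_over_input_gives_x_two(self):
        regions = self._regions(3)
        counts = np.array([399.0, 799.0, 1599.0])  # +1 pseudocount -> 400/800/1600
        inputs = np.array([99.0, 199.0, 399.0])
        recs = diff_plot_coordinates(
            regions,
            RegionCounts(counts, 10_000),
            [RegionCounts(counts, 10_000), RegionCounts(counts, 10_000)],
            [RegionCounts(inputs, 10_000), RegionCounts(inputs, 10_000)],
        )
        assert [r.x for r in recs] == pytest.approx([2.0, 2.0, 2.0])

    def test_k27m_at_geometric_mean_gives_y_zero(self):
        regions = self._regions(1)
        wt1 = RegionCounts(np.array([99.0]), 1000)  # processed 0.1
        wt2 = RegionCounts(np.array([399.0]), 1000)  # processed 0.4
        k27m = RegionCounts(np.array([199.0]), 1000)  # processed 0.2 = gmean
        inp = RegionCounts(np.array([99.0]), 1000)
        (rec,) = diff_plot_coordinates(regions, k27m, [wt1, wt2], [inp, inp])
        assert rec.y == pytest.approx(0.0, abs=1e-12)

    def test_single_wt_matches_log_ratio_oracle(self):
        rng = np.random.default_rng(21)
        n = 50
        regions = self._regions(n)
        c = 1.0
        k27m = RegionCounts(rng.integers(0, 500, n).astype(float), 40_000, rx=0.2)
        wt = RegionCounts(rng.integers(0, 500, n).astype(float), 60_000, rx=1.1)
        inp = RegionCounts(rng.integers(0, 500, n).astype(float), 55_000)
        recs = diff_plot_coordinates(regions, k27m, [wt], [inp], pseudocount=c)
        for i, rec in enumerate(recs):
            wt_p = wt.rx * (wt.counts[i] + c) / wt.total_reads
            in_p = (inp.counts[i] + c) / inp.total_reads
            k_p = k27m.rx * (k27m.counts[i] + c) / k27m.total_reads
            assert rec.x == pytest.approx(np.log2(wt_p / in_p))
            assert rec.y == pytest.approx(np.log2(k_p / wt_p))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            diff_plot_coordinates(
                self._regions(2),
                RegionCounts(np.zeros(3), 10),
                [RegionCounts(np.zeros(2), 10)],
                [RegionCounts(np.zeros(2), 10)],
            )


def _rec(x, y):
    return DiffPlotRecord(GenomicInterval("chrA", 0, 1), x, y)


class TestCategorize:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            (2.0, 0.5, "Gained"),
            (-4.0, -1.0, "Absent"),
            (0.0, -5.0, "Lost"),
            (2.0, -1.5, "Retained"),
            (0.0, -0.5, "Unclassified"),
        ],
    )
    def test_bt245_cgi_regions(self, x, y, expected):
        (rec,) = categorize([_rec(x, y)], PRESET_THRESHOLDS["BT245-CGI"])
        assert rec.category == expected

    def test_bt245_cgi_regions_pairwise_disjoint(self):
        thr = PRESET_THRESHOLDS["BT245-CGI"]
        xs = np.linspace(-8, 8, 81)
        ys = np.linspace(-8, 8, 81)
        for x in xs:
            for y in ys:
                hits = [c for c, b in thr.bounds if b.contains(x, y)]
                assert len(hits) <= 1, (x, y, hits)

    def test_dipgxiii_overlap_resolved_by_order(self):
        # (x=1, y=3) satisfies both the Gained (y>2.6) and Retained
        # (y>-2, x>0.5) printed bounds; Gained is evaluated first
        (rec,) = categorize([_rec(1.0, 3.0)], PRESET_THRESHOLDS["DIPGXIII-CGI"])
        assert rec.category == "Gained"

    def test_boundaries_are_strict(self):
        (rec,) = categorize([_rec(2.0, 0.0)], PRESET_THRESHOLDS["BT245-CGI"])
        assert rec.category == "Unclassified"

    def test_yaml_roundtrip(self, tmp_path):
        import yaml

        path = tmp_path / "thr.yaml"
        path.write_text(
            yaml.safe_dump(
                {
                    "name": "custom",
                    "order": ["Gained", "Absent", "Lost", "Retained"],
                    "categories": {
                        "Gained": {"y_gt": 0.0},
                        "Absent": {"y_lt": 0.0, "x_lt": -3.75},
                        "Lost": {"y_lt": -4.0, "x_gt": -2.5},
                        "Retained": {"y_gt": -3.0, "y_lt": 0.0, "x_gt": 1.25},
                    },
                }
            )
        )
        thr = load_thresholds(path)
        for x, y in [(2.0, 0.5), (-4.0, -1.0), (0.0, -5.0), (2.0, -1.5)]:
            (a,) = categorize([_rec(x, y)], thr)
            (b,) = categorize([_rec(x, y)], PRESET_THRESHOLDS["BT245-CGI"])
            assert a.category == b.category


class TestSpreadCorrelation:
    def _tracks(self, n_bins, seed=0):
        part = make_bins(GenomeDescription((("chrA", n_bins * 1000),)), 1000)
        rng = np.random.default_rng(seed)
        return part, [_track(part, rng.normal(size=n_bins)) for _ in range(3)]

    def test_two_bins_per_window(self):
        _, (a, b, c) = self._tracks(2000)
        windows = spread_correlation(a, b, c, n_windows=1000)
        assert len(windows) == 1000
        assert all(w.n_bins == 2 for w in windows)

    def test_identical_tracks_identical_means(self):
        _, (a, _, c) = self._tracks(1500)
        windows = spread_correlation(a, a, c, n_windows=100)
        for w in windows:
            assert w.mean_wt_me3 == pytest.approx(w.mean_k27m_me2)

    def test_ranking_track_monotone_non_increasing(self):
        _, (a, b, c) = self._tracks(5000, seed=3)
        windows = spread_correlation(a, b, c, n_windows=250)
        means = [w.mean_k27m_me2 for w in windows]
        assert all(x >= y for x, y in zip(means, means[1:]))

    def test_sizes_differ_by_at_most_one_and_conserve(self):
        _, (a, b, c) = self._tracks(2713, seed=4)
        windows = spread_correlation(a, b, c, n_windows=1000)
        sizes = {w.n_bins for w in windows}
        assert max(sizes) - min(sizes) <= 1
        assert sum(w.n_bins for w in windows) == 2713

    def test_fewer_bins_than_windows_rejected(self):
        _, (a, b, c) = self._tracks(500)
        with pytest.raises(ValueError, match="fewer bins"):
            spread_correlation(a, b, c, n_windows=1000)


class TestAggregateProfile:
    def test_single_anchor_equals_signal_slice(self):
        part = make_bins(GenomeDescription((("chrA", 100_000),)), 500)
        vals = np.arange(200.0)
        track = _track(part, vals)
        anchor = GenomicInterval("chrA", 49_000, 51_000)  # midpoint 50_000
        prof = aggregate_profile(track, [anchor], flank=5_000, bin_width=500)
        start_bin = (50_000 - 5_000) // 500
        np.testing.assert_allclose(
            prof.mean_signal, vals[start_bin : start_bin + 20]
        )

    def test_flat_track_flat_profile(self):
        part = make_bins(GenomeDescription((("chrA", 200_000),)), 500)
        track = _track(part, np.full(400, 3.25))
        anchors = [GenomicInterval("chrA", s, s + 1000) for s in (30_000, 90_000)]
        prof = aggregate_profile(track, anchors, flank=10_000, bin_width=500)
        np.testing.assert_allclose(prof.mean_signal, 3.25)
        assert prof.n_anchors == 2

    def test_offsets_symmetric_about_zero(self):
        part = make_bins(GenomeDescription((("chrA", 100_000),)), 500)
        prof = aggregate_profile(
            _track(part, np.zeros(200)),
            [GenomicInterval("chrA", 40_000, 60_000)],
            flank=5_000,
            bin_width=500,
        )
        np.testing.assert_array_equal(prof.offsets, -prof.offsets[::-1])

    def test_out_of_bounds_offsets_excluded_from_mean(self):
        part = make_bins(GenomeDescription((("chrA", 20_000),)), 500)
        track = _track(part, np.full(40, 2.0))
        # anchor near the chromosome start: upstream offsets fall outside
        prof = aggregate_profile(
            track, [GenomicInterval("chrA", 0, 2_000)], flank=5_000, bin_width=500
        )
        assert np.isnan(prof.mean_signal[:8]).all()
        np.testing.assert_allclose(prof.mean_signal[10:], 2.0)

    def test_empty_anchor_list_rejected(self):
        part = make_bins(GenomeDescription((("chrA", 1_000),)), 500)
        with pytest.raises(ValueError, match="empty"):
            aggregate_profile(_track(part, np.zeros(2)), [], 500, 500)

    def test_synthetic_peak_maximal_at_center(self, default_config, dataset):
        from epispread.normalize import input_normalize, track_from_tags
        from epispread.genome import make_bins as mb

        part = mb(default_config.genome, 500)
        norm = input_normalize(
            track_from_tags(dataset.samples[("K27M", "me3")], part),
            track_from_tags(dataset.samples[("K27M", "input")], part),
        )
        prof = aggregate_profile(
            norm, dataset.annotations.suz12_peaks, flank=20_000, bin_width=500
        )
        center = np.argmin(np.abs(prof.offsets))
        # the maximum lies inside the focal peak plateau around the anchor
        assert abs(prof.offsets[prof.mean_signal.argmax()]) <= default_config.peak_width
        # signal decays beyond the focal peak width
        far = np.abs(prof.offsets) > default_config.peak_width + 5_000
        assert prof.mean_signal[far].max() < prof.mean_signal[center] / 2


class TestRegionScaledProfile:
    def test_flat_track_flat_everywhere(self):
        part = make_bins(GenomeDescription((("chrA", 500_000),)), 500)
        track = _track(part, np.full(1000, 1.5))
        regions = [
            GenomicInterval("chrA", 100_000, 180_000),
            GenomicInterval("chrA", 300_000, 340_000),
        ]
        coords, means = region_scaled_profile(track, regions, flank=20_000)
        np.testing.assert_allclose(means, 1.5)
        assert coords[0] == -1.0 and coords[-1] < 2.0

    def test_body_signal_separated_from_flanks(self):
        part = make_bins(GenomeDescription((("chrA", 500_000),)), 500)
        vals = np.zeros(1000)
        vals[200:400] = 4.0  # region body 100k-200k
        track = _track(part, vals)
        coords, means = region_scaled_profile(
            track, [GenomicInterval("chrA", 100_000, 200_000)], flank=20_000
        )
        body = (coords >= 0) & (coords < 1)
        np.testing.assert_allclose(means[body], 4.0)
        assert means[coords < -0.1].max() == 0.0


class TestSignalMatrixKmeans:
    def _setup(self, n_regions=30, seed=0):
        part = make_bins(GenomeDescription((("chrA", 1_000_000),)), 1000)
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=1000)
        regions = [
            GenomicInterval("chrA", int(s), int(s) + 2_000)
            for s in np.linspace(50_000, 900_000, n_regions)
        ]
        return _track(part, vals), regions

    def test_k_one_single_cluster(self):
        track, regions = self._setup()
        _, labels, _ = signal_matrix_kmeans([track], regions, flank=5_000, k=1)
        assert set(labels) == {0}

    def test_separated_classes_recovered(self):
        part = make_bins(GenomeDescription((("chrA", 1_000_000),)), 1000)
        vals = np.zeros(1000)
        vals[:500] = 10.0  # first half of the genome strongly marked
        track = _track(part, vals)
        high = [GenomicInterval("chrA", s, s + 2_000) for s in range(100_000, 300_000, 20_000)]
        low = [GenomicInterval("chrA", s, s + 2_000) for s in range(700_000, 900_000, 20_000)]
        _, labels, order = signal_matrix_kmeans(
            [track], high + low, flank=5_000, k=2, seed=0
        )
        assert len(set(labels[: len(high)])) == 1
        assert len(set(labels[len(high) :])) == 1
        assert labels[0] != labels[-1]
        # ordering puts the strong cluster first
        assert set(order[: len(high)]) == set(range(len(high)))

    def test_label_count_bounded_by_k(self):
        track, regions = self._setup(seed=5)
        _, labels, _ = signal_matrix_kmeans([track], regions, flank=5_000, k=3)
        assert len(set(labels)) <= 3

    def test_k_exceeding_regions_rejected(self):
        track, regions = self._setup(n_regions=2)
        with pytest.raises(ValueError, match="exceeds"):
            signal_matrix_kmeans([track], regions, flank=5_000, k=3)

    def test_fixed_seed_reproducible(self):
        track, regions = self._setup(seed=9)
        _, l1, o1 = signal_matrix_kmeans([track], regions, flank=5_000, k=3, seed=42)
        _, l2, o2 = signal_matrix_kmeans([track], regions, flank=5_000, k=3, seed=42)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(o1, o2)


def test_category_thresholds_reject_duplicates():
    with pytest.raises(ValueError, match="duplicate"):
        CategoryThresholds(
            "bad",
            (("Gained", CategoryBounds(y_gt=0)), ("Gained", CategoryBounds(y_lt=0))),
        )
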