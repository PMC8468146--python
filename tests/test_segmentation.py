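"""Synchronization, thresholding and interval arithmetic."""

import numpy as np
import pytest

from ridgelab import (Interval, IntervalSet, Ridge, adaptive_threshold,
                      intersect_interval_sets, pairwise_sync,
                      record_sync_intervals, segment_pipeline, sync_fragments,
                      threshold_segments)
from ridgelab.segmentation import SyncSeries
from ridgelab.synth import Episode, PlantedRecordSpec, gen_monitoring_record


def make_ridge(fr, fs=10.0, psd=None, valid=None, channel="A"):
    fr = np.asarray(fr, dtype=float)
    n = fr.size
    return Ridge(
        times=np.arange(n) / fs,
        fr=fr,
        modulus=np.sqrt(psd) if psd is not None else np.ones(n),
        psd=np.asarray(psd, dtype=float) if psd is not None else np.ones(n),
        phase=np.zeros(n),
        valid=np.ones(n, bool) if valid is None else valid,
        channel=channel,
    )


def make_sync(mask, fs=1.0, pair=("A", "B")):
    mask = np.asarray(mask, bool)
    return SyncSeries(pair, mask, np.arange(mask.size) / fs, 0.5)


class TestPairwiseSync:
    def test_identical_channels_always_synced(self):
        r = make_ridge(np.linspace(2, 4, 50))
        s = pairwise_sync(r, make_ridge(np.linspace(2, 4, 50), channel="B"))
        assert s.sync.all()

    def test_boundary_is_inclusive(self):
        # 2 and 2.5 Hz sit exactly epsilon apart and count as synchronized
        s = pairwise_sync(make_ridge(np.full(30, 2.0)),
                          make_ridge(np.full(30, 2.5), channel="B"), epsilon=0.5)
        assert s.sync.all()

    def test_separated_tones_never_sync(self):
        s = pairwise_sync(make_ridge(np.full(30, 2.0)),
                          make_ridge(np.full(30, 4.0), channel="B"), epsilon=0.5)
        assert not s.sync.any()

    def test_invalid_samples_excluded(self):
        valid = np.ones(30, bool)
        valid[5:10] = False
        s = pairwise_sync(make_ridge(np.full(30, 3.0), valid=valid),
                          make_ridge(np.full(30, 3.0), channel="B"))
        assert not s.sync[5:10].any() and s.sync[10:].all()

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        fa, fb = 3 + rng.random(100), 3 + rng.random(100)
        s_ab = pairwise_sync(make_ridge(fa), make_ridge(fb, channel="B"))
        s_ba = pairwise_sync(make_ridge(fb, channel="B"), make_ridge(fa))
        np.testing.assert_array_equal(s_ab.sync, s_ba.sync)

    def test_mismatched_time_base_rejected(self):
        with pytest.raises(ValueError, match="time base"):
            pairwise_sync(make_ridge(np.full(30, 3.0)),
                          make_ridge(np.full(40, 3.0)))


class TestSyncFragments:
    def test_short_gap_merges_runs(self):
        mask = np.zeros(25, bool)
        mask[0:6] = True    # [0, 6) s
        mask[12:20] = True  # [12, 20) s: gap of 6 s < 10 s
        out = sync_fragments(make_sync(mask))
        assert len(out) == 1
        assert out.intervals[0].start == 0.0 and out.intervals[0].end == 20.0

    def test_short_fragment_dropped(self):
        mask = np.zeros(30, bool)
        mask[0:8] = True
        assert len(sync_fragments(make_sync(mask))) == 0

    def test_all_zero_gives_empty(self):
        assert len(sync_fragments(make_sync(np.zeros(50, bool)))) == 0

    def test_merge_happens_before_duration_filter(self):
        # two 6 s runs, 6 s apart: each alone is too short, merged they stay
        mask = np.zeros(30, bool)
        mask[0:6] = True
        mask[12:18] = True
        out = sync_fragments(make_sync(mask))
        assert len(out) == 1 and out.intervals[0].duration >= 10

    def test_output_durations_respect_min_dur(self):
        rng = np.random.default_rng(1)
        mask = rng.random(600) < 0.3
        out = sync_fragments(make_sync(mask))
        assert all(iv.duration >= 10.0 for iv in out)


class TestRecordSyncIntervals:
    def test_single_pair_passthrough(self):
        mask = np.zeros(40, bool)
        mask[0:20] = True
        quiet = np.zeros(40, bool)
        out = record_sync_intervals([make_sync(mask), make_sync(quiet, pair=("C", "D"))])
        assert len(out) == 1
        iv = out.intervals[0]
        assert (iv.start, iv.end) == (0.0, 20.0)
        assert "A-B" in iv.label

    def test_min_pairs_two_requires_simultaneity(self):
        m1 = np.zeros(40, bool); m1[0:20] = True    # fragment [0, 20)
        m2 = np.zeros(40, bool); m2[10:30] = True   # fragment [10, 30)
        out = record_sync_intervals([make_sync(m1), make_sync(m2, pair=("C", "D"))],
                                    min_pairs=2)
        assert len(out) == 1
        assert (out.intervals[0].start, out.intervals[0].end) == (10.0, 20.0)

    def test_min_pairs_above_available_gives_empty(self):
        m = np.zeros(40, bool); m[0:20] = True
        assert len(record_sync_intervals([make_sync(m)], min_pairs=5)) == 0

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(2)
        series = [make_sync(rng.random(200) < 0.4, pair=(f"P{i}", f"Q{i}"))
                  for i in range(4)]
        for min_pairs in (1, 2, 3):
            out = record_sync_intervals(series, min_pairs,
                                        merge_gap=5.0, min_dur=3.0)
            # dense oracle at 1 ms resolution
            grid = np.arange(0, 200, 0.001)
            count = np.zeros(grid.size)
            for s in series:
                frs = sync_fragments(s, 5.0, 3.0)
                for iv in frs:
                    count[(grid >= iv.start) & (grid < iv.end)] += 1
            want = count >= min_pairs
            got = np.zeros(grid.size, bool)
            for iv in out:
                got |= (grid >= iv.start) & (grid < iv.end)
            assert np.array_equal(want, got)


class TestThresholdSegments:
    def test_all_below_threshold_empty(self):
        r = make_ridge(np.full(100, 3.0), psd=np.full(100, 1.0))
        assert len(threshold_segments(r, 2.0)) == 0

    def test_three_bursts_three_intervals(self):
        psd = np.full(300, 1.0)
        psd[40:60] = psd[140:160] = psd[240:260] = 50.0
        r = make_ridge(np.full(300, 3.0), psd=psd)
        assert len(threshold_segments(r, 10.0)) == 3

    def test_threshold_below_minimum_spans_record(self):
        r = make_ridge(np.full(100, 3.0), psd=np.full(100, 5.0))
        out = threshold_segments(r, 1e-9)
        assert len(out) == 1
        assert out.intervals[0].duration == pytest.approx(10.0)


def planted_psd_ridge(seed, n=20000, fs=10.0, n_bursts=5, burst_scale=100.0):
    """Gaussian-noise ridge PSD with planted flat bursts; returns burst mask."""
    rng = np.random.default_rng(seed)
    psd = np.abs(rng.normal(0, 1.0, n)) + 0.1
    burst = np.zeros(n, bool)
    for s in (np.linspace(0.1, 0.85, n_bursts) * n).astype(int):
        psd[s:s + int(20 * fs)] += burst_scale * (1 + 0.2 * rng.random())
        burst[s:s + int(20 * fs)] = True
    return make_ridge(np.full(n, 3.0), fs=fs, psd=psd), burst


class TestAdaptiveThreshold:
    def test_planted_bursts_recovered_exactly(self):
        r, burst = planted_psd_ridge(0)
        scan = adaptive_threshold(r)
        assert scan.knee_found
        assert r.psd[~burst].max() < scan.chosen < r.psd[burst].min()
        assert len(threshold_segments(r, scan.chosen)) == 5

    def test_constant_psd_warns_and_falls_back(self):
        r = make_ridge(np.full(1000, 3.0), psd=np.full(1000, 1.0))
        with pytest.warns(RuntimeWarning, match="no knee"):
            scan = adaptive_threshold(r)
        assert not scan.knee_found
        assert scan.thresholds[0] <= scan.chosen <= scan.thresholds[-1]

    def test_scale_equivariance(self):
        r, _ = planted_psd_ridge(3)
        s1 = adaptive_threshold(r)
        r2 = make_ridge(r.fr, psd=2 * r.psd)
        s2 = adaptive_threshold(r2)
        assert s2.chosen == pytest.approx(2 * s1.chosen)

    def test_smoothed_counts_non_increasing_above_noise_mode(self):
        # between the noise mode and the burst floor the count curve only
        # collapses and flattens; (the flat-topped test bursts shatter when
        # the threshold crosses their own tops, outside this domain)
        r, burst = planted_psd_ridge(4)
        scan = adaptive_threshold(r)
        start = int(np.argmax(scan.smoothed))  # the noise mode of the curve
        sel = np.arange(scan.thresholds.size) >= start
        # stop half a smoothing window short of the burst floor: the moving
        # average leaks the bursts' own collapse backwards by that margin
        step = scan.thresholds[1] - scan.thresholds[0]
        sel &= scan.thresholds < r.psd[burst].min() - 3 * step
        diffs = np.diff(scan.smoothed[sel])
        assert diffs.max() <= 0.5

    def test_too_few_scan_points_rejected(self):
        r, _ = planted_psd_ridge(5)
        with pytest.raises(ValueError):
            adaptive_threshold(r, scan_points=2)


class TestIntersect:
    def test_simple_overlap(self):
        out = intersect_interval_sets(IntervalSet([Interval(0, 10, "a")]),
                                      IntervalSet([Interval(5, 15, "b")]))
        assert len(out) == 1
        iv = out.intervals[0]
        assert (iv.start, iv.end) == (5.0, 10.0)
        assert iv.label == "a&b"

    def test_disjoint_sets_empty(self):
        out = intersect_interval_sets(IntervalSet([Interval(0, 5, "a")]),
                                      IntervalSet([Interval(6, 9, "b")]))
        assert len(out) == 0

    def test_matches_dense_rasterization_oracle(self):
        rng = np.random.default_rng(6)

        def random_set(k):
            ivs = []
            for _ in range(k):
                s = rng.uniform(0, 50)
                ivs.append(Interval(round(s, 3), round(s + rng.uniform(0.05, 6), 3), "x"))
            return IntervalSet(ivs).normalize()

        grid = np.arange(0, 60, 0.001)
        for _ in range(50):
            a, b = random_set(6), random_set(6)
            out = intersect_interval_sets(a, b)
            ra = np.zeros(grid.size, bool)
            rb = np.zeros(grid.size, bool)
            ro = np.zeros(grid.size, bool)
            for iv in a:
                ra |= (grid >= iv.start) & (grid < iv.end)
            for iv in b:
                rb |= (grid >= iv.start) & (grid < iv.end)
            for iv in out:
                ro |= (grid >= iv.start) & (grid < iv.end)
            assert np.array_equal(ra & rb, ro)

    def test_commutative_and_associative(self):
        a = IntervalSet([Interval(0, 10, "a"), Interval(20, 30, "a")])
        b = IntervalSet([Interval(5, 25, "b")])
        c = IntervalSet([Interval(8, 22, "c")])

        def spans(s):
            return [(iv.start, iv.end) for iv in s.normalize()]

        assert spans(intersect_interval_sets(a, b)) == spans(intersect_interval_sets(b, a))
        left = intersect_interval_sets(intersect_interval_sets(a, b), c)
        right = intersect_interval_sets(a, intersect_interval_sets(b, c))
        assert spans(left) == spans(right)


class TestSegmentPipeline:
    """Short-record pipeline checks; the full-length study runs elsewhere."""

    @staticmethod
    def small_record(seed, episodes):
        spec = PlantedRecordSpec(n_channels=4, fs=256.0, duration=300.0,
                                 episodes=episodes, seed=seed,
                                 labels=["Fp1", "Fp2", "C3", "C4"])
        return gen_monitoring_record(spec)

    def test_planted_episode_recovered(self):
        rec, truth = self.small_record(
            0, [Episode(120, 150, "spike_wave", ("Fp1", "Fp2"), {"rate": 2.0})])
        hits, report = segment_pipeline(rec)
        assert len(hits) == 1
        assert hits.intervals[0].overlaps(truth.intervals[0])
        assert report.retained_duration <= min(report.sync_duration,
                                               report.psd_duration) + 1e-9

    def test_single_channel_burst_not_reported(self):
        rec, _ = self.small_record(
            1, [Episode(120, 150, "spike_wave", ("C3",), {"rate": 2.0})])
        hits, _ = segment_pipeline(rec)
        assert len(hits) == 0

    def test_needs_two_channels(self):
        rec, _ = self.small_record(2, [])
        rec1 = type(rec)(rec.samples[:1], rec.fs, rec.labels[:1])
        with pytest.raises(ValueError):
            segment_pipeline(rec1)
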