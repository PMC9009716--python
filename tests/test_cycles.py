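"""Cycle detection: dynamic range, peak picking, cycle building, exclusions."""

import numpy as np
import pytest

import gawkit as gk
from gawkit.cycles import Cycle, _round_half_up
from conftest import brute_detect_peaks, brute_local_maxima, brute_prominence


def _sine(freq=100.0, amp=1.0, n=3000, frame_rate=3000.0, trend=0.0):
    # cosine phase: extrema fall exactly on sample points for 100 Hz / 3000 fps
    t = np.arange(n) / frame_rate
    return amp * np.cos(2 * np.pi * freq * t) + trend * t


class TestMaxDynamicRange:
    def test_sine_reaches_full_peak_to_trough(self):
        # period 10 ms <= 25 ms: the trough is reachable within the window
        x = _sine(freq=100.0, amp=3.0)
        assert gk.max_dynamic_range(x) == pytest.approx(6.0, rel=1e-3)

    def test_monotone_ramp_has_no_maximum(self):
        with pytest.raises(ValueError):
            gk.max_dynamic_range(np.linspace(0, 10, 500))

    def test_trended_sine_bounded_and_matches_exhaustive_scan(self):
        x = _sine(freq=100.0, amp=2.0, trend=20.0)  # +0.5 area per 25 ms window
        got = gk.max_dynamic_range(x)
        d = 20.0 * 0.025
        assert 4.0 - 1e-6 <= got <= 4.0 + d + 1e-6
        w = _round_half_up(12.5 * 3000.0 / 1000.0)
        brute = max(
            x[m] - np.min(x[max(0, m - w): m + w + 1])
            for m in brute_local_maxima(x)
        )
        assert got == pytest.approx(brute, abs=0)

    def test_window_rounding_is_half_up(self):
        assert _round_half_up(12.5 * 3000.0 / 1000.0) == 38


class TestDetectPeaks:
    def test_equal_peaks_at_minimum_distance_both_kept(self):
        x = np.zeros(100)
        x[[40, 43]] = 50.0
        assert list(gk.detect_peaks(x)) == [40, 43]

    def test_equal_peaks_below_minimum_distance_keep_earlier(self):
        x = np.zeros(100)
        x[[40, 42]] = 50.0
        assert list(gk.detect_peaks(x)) == [40]

    def test_taller_peak_wins_below_minimum_distance(self):
        x = np.zeros(100)
        x[40] = 50.0
        x[42] = 60.0
        assert list(gk.detect_peaks(x)) == [42]

    def test_subthreshold_ripple_rejected(self):
        x = np.zeros(600)
        for m in (50, 150, 250):
            x[m - 10: m] = np.linspace(0, 100, 11)[:-1]
            x[m: m + 11] = np.linspace(100, 0, 11)
        x[[400, 450, 500]] = 4.0  # 4% of the maximum dynamic range
        got = set(gk.detect_peaks(x))
        assert {50, 150, 250} <= got
        assert got.isdisjoint({400, 450, 500})
        # calibrated against the from-scratch prominence computation
        for m in (400, 450, 500):
            assert brute_prominence(x, m) == pytest.approx(4.0)

    def test_strictly_monotone_series_yields_nothing(self):
        assert len(gk.detect_peaks(np.arange(100.0))) == 0

    def test_matches_bruteforce_on_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(20, 180))
            x = rng.normal(0, 1, n).cumsum() + rng.normal(0, 0.5, n)
            try:
                got = list(gk.detect_peaks(x))
            except ValueError:
                assert not brute_local_maxima(x)
                continue
            assert got == brute_detect_peaks(x)


class TestBuildCycles:
    def test_consecutive_peak_pairs_become_cycles(self):
        cycles = gk.build_cycles([10, 20, 31], np.cos(np.arange(40) * 0.63))
        assert [(c.start_frame, c.end_frame) for c in cycles] == [(10, 20), (20, 31)]
        assert [c.length_frames for c in cycles] == [10, 11]

    def test_symmetric_trough_falls_at_midpoint(self):
        x = np.cos(2 * np.pi * np.arange(41) / 20.0)
        (cycle,) = gk.build_cycles([0, 20], x)
        assert cycle.min_frame == 10

    def test_tied_minima_take_earliest(self):
        x = np.array([5.0, 3, 1, 1, 3, 5, 3, 1, 1, 3, 5])
        cycles = gk.build_cycles([0, 5, 10], x)
        for c in cycles:
            interior = x[c.start_frame + 1: c.end_frame]
            assert c.min_frame == c.start_frame + 1 + int(np.argmin(interior))
        assert cycles[0].min_frame == 2

    def test_fewer_than_two_peaks_give_no_cycles(self):
        assert gk.build_cycles([7], np.zeros(20)) == []


class TestExcludeDamaged:
    def _cycles(self):
        return gk.build_cycles([0, 10, 20, 30], np.cos(np.arange(31) * 0.63))

    def test_clean_mask_keeps_everything(self):
        mask = np.zeros(31, dtype=bool)
        assert all(c.valid for c in gk.exclude_damaged(self._cycles(), mask))

    def test_single_damaged_frame_hits_exactly_one_cycle(self):
        mask = np.zeros(31, dtype=bool)
        mask[15] = True
        flags = [c.valid for c in gk.exclude_damaged(self._cycles(), mask)]
        assert flags == [True, False, True]

    def test_run_spanning_a_boundary_hits_both_cycles(self):
        mask = np.zeros(31, dtype=bool)
        mask[9:12] = True
        flags = [c.valid for c in gk.exclude_damaged(self._cycles(), mask)]
        assert flags == [False, False, True]

    def test_boundary_frame_belongs_to_next_cycle(self):
        mask = np.zeros(31, dtype=bool)
        mask[10] = True  # shared boundary: half-open [start, end)
        flags = [c.valid for c in gk.exclude_damaged(self._cycles(), mask)]
        assert flags == [True, False, True]


class TestOutlierRemoval:
    def _make(self, lengths):
        start = 0
        cycles = []
        for L in lengths:
            cycles.append(Cycle(start, start + L, start + L // 2))
            start += L
        return cycles

    def test_equal_lengths_have_no_outliers(self):
        out = gk.remove_outlier_cycles(self._make([10] * 30))
        assert all(c.valid for c in out)

    def test_isolated_long_cycle_flagged(self):
        out = gk.remove_outlier_cycles(self._make([10] * 10 + [25] + [10] * 10))
        reasons = [c.exclusion_reason for c in out]
        assert reasons[10] == "outlier"
        assert reasons.count("outlier") == 1

    def test_gradual_drift_not_flagged(self):
        lengths = [round(10 * (1 + 0.1 * np.sin(i / 5))) for i in range(60)]
        assert all(c.valid for c in gk.remove_outlier_cycles(self._make(lengths)))

    def test_octave_drop_survives_boundary_ratio(self):
        # a genuine mode change doubles the cycle length; 2.0x the local
        # median is kept (inclusive boundary)
        lengths = [7, 8] * 15 + [15] * 30
        out = gk.remove_outlier_cycles(self._make(lengths))
        assert all(c.valid for c in out)

    def test_matches_single_pass_bruteforce(self):
        rng = np.random.default_rng(7)
        lengths = list(rng.integers(5, 30, 50))
        out = gk.remove_outlier_cycles(self._make(lengths), window=11)
        arr = np.array(lengths, float)
        for i, c in enumerate(out):
            lo, hi = max(0, i - 5), min(len(arr), i + 6)
            med = np.median(arr[lo:hi])
            expect = arr[i] < 0.5 * med - 1e-9 or arr[i] > 2.0 * med + 1e-9
            assert (not c.valid) == expect

    def test_damaged_flags_preserved(self):
        cycles = self._make([10] * 10 + [25] + [10] * 10)
        cycles[3] = Cycle(cycles[3].start_frame, cycles[3].end_frame,
                          cycles[3].min_frame, valid=False,
                          exclusion_reason="damaged")
        out = gk.remove_outlier_cycles(cycles)
        assert out[3].exclusion_reason == "damaged"
        assert out[10].exclusion_reason == "outlier"


def test_cycles_tile_the_peak_sequence(clean_tone):
    peaks = gk.detect_peaks(clean_tone.total)
    cycles = gk.build_cycles(peaks, clean_tone.total)
    for a, b in zip(cycles, cycles[1:]):
        assert a.end_frame == b.start_frame
        assert a.start_frame < a.min_frame < a.end_frame
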