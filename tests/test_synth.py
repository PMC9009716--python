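"""Synthetic phonation generator: construction guarantees and grid rules."""

import numpy as np
import pytest

import gawkit as gk
from conftest import brute_local_maxima


def _noiseless(**kw):
    base = dict(jitter_sd=0.0, shimmer_sd=0.0, noise_sd=0.0, baseline=0.0)
    base.update(kw)
    return gk.SynthConfig(**base)


class TestGenerateGaw:
    def test_constant_f0_gives_one_maximum_per_period(self, clean_tone):
        # 300 Hz for 1 s: one interior maximum every 10 frames, boundary
        # cycles may add or drop one
        maxima = brute_local_maxima(clean_tone.total)
        assert 299 <= len(maxima) <= 301

    def test_symmetric_split_without_lag_gives_identical_partials(self):
        rec = gk.generate_gaw(_noiseless(duration=0.5, phase_lag=0.0,
                                         left_right_split=0.5))
        np.testing.assert_array_equal(rec.left, rec.right)
        np.testing.assert_allclose(rec.left + rec.right, rec.total)

    def test_f0_step_changes_peak_spacing(self):
        # 400 Hz -> 200 Hz at 0.5 s: maximum-to-maximum spacing measured
        # independently must read 7-8 frames before and 15 after
        rec = gk.generate_gaw(_noiseless(
            duration=1.0, f0_schedule=((0.0, 400.0), (0.5, 200.0))))
        maxima = np.array(brute_local_maxima(rec.total))
        spacing = np.diff(maxima)
        mid = np.searchsorted(maxima, 1500)
        assert set(spacing[: mid - 1]) <= {7, 8}
        assert set(spacing[mid + 1:]) <= {15}

    def test_partials_always_sum_to_total(self):
        rec = gk.generate_gaw(gk.SynthConfig(duration=0.5, phase_lag=0.1,
                                             noise_sd=5.0, seed=3))
        np.testing.assert_allclose(rec.left + rec.right, rec.total, rtol=0, atol=0)

    def test_same_seed_reproduces_bit_identical_output(self):
        a = gk.generate_gaw(gk.SynthConfig(duration=0.5, seed=7))
        b = gk.generate_gaw(gk.SynthConfig(duration=0.5, seed=7))
        c = gk.generate_gaw(gk.SynthConfig(duration=0.5, seed=8))
        np.testing.assert_array_equal(a.total, b.total)
        assert not np.array_equal(a.total, c.total)

    def test_dynamic_range_is_monotone_without_shimmer(self):
        # 300 Hz aligns cycle boundaries with the frame grid so the sampled
        # peak heights track the amplitude ramp without quantization ripple
        rec = gk.generate_gaw(gk.SynthConfig(
            duration=1.0, f0_schedule=((0.0, 300.0),), jitter_sd=0.0,
            shimmer_sd=0.0, noise_sd=0.0, seed=2))
        peaks = gk.detect_peaks(rec.total)
        cycles = gk.build_cycles(peaks, rec.total)
        drs = [gk.compute_dr(c, rec.total) for c in cycles]
        assert np.all(np.diff(drs) >= -1e-6)

    def test_damaged_runs_marked_in_mask(self):
        rec = gk.generate_gaw(gk.SynthConfig(
            duration=0.5, damaged_runs=((100, 10), (600, 19))))
        assert rec.damaged_mask[100:110].all()
        assert rec.damaged_mask[600:619].all()
        assert rec.damaged_mask.sum() == 29

    @pytest.mark.parametrize("bad", [
        dict(f0_schedule=((0.0, 900.0),)),          # cycle < 4 frames
        dict(f0_schedule=((0.0, 2000.0),)),         # above Nyquist
        dict(damaged_runs=((0, 25),)),              # run longer than 20
        dict(duration=0.10001),                     # non-integral frame count
        dict(phase_lag=0.7),
        dict(left_right_split=0.0),
        dict(jitter_sd=-0.1),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            gk.generate_gaw(gk.SynthConfig(**bad))

    def test_single_sustained_step_in_cycle_lengths(self):
        # programmed-event recoverability: with no jitter the cycle-length
        # sequence contains exactly one level shift
        rec = gk.generate_gaw(_noiseless(
            duration=1.0, f0_schedule=((0.0, 400.0), (0.5, 200.0))))
        spacing = np.diff(brute_local_maxima(rec.total))
        levels = np.where(spacing > 11, 1, 0)
        assert np.sum(np.abs(np.diff(levels))) == 1


class TestGrid:
    def test_default_grid_has_320_cells(self):
        records = gk.generate_grid(gk.GridConfig(seed=0, damage_fraction=0.0))
        assert len(records) == 320

    def test_event_rule_never_programs_no_events(self):
        records = gk.generate_grid(gk.GridConfig(
            seed=0, event_rule=lambda s, l, r: False, damage_fraction=0.0))
        for rec in records.values():
            if rec is not None:
                assert rec.truth["n_programmed_events"] == 0

    def test_programmed_event_count_matches_predicate_enumeration(self):
        rule = lambda s, l, r: s >= 1 and l == r >= 5
        grid = gk.GridConfig(seed=0, onset_rule=lambda *a: True,
                             event_rule=rule, damage_fraction=0.0)
        records = gk.generate_grid(grid)
        expected = sum(rule(*c) and c[0] >= 1 for c in grid.conditions())
        actual = sum(rec.truth["n_programmed_events"]
                     for rec in records.values() if rec is not None)
        assert actual == expected == 12  # 4 SLN levels x 3 symmetric pairs

    def test_sln_zero_cells_never_contain_events(self):
        records = gk.generate_grid(gk.GridConfig(
            seed=0, onset_rule=lambda *a: True,
            event_rule=lambda *a: True, damage_fraction=0.0))
        for cond, rec in records.items():
            if cond.sln == 0:
                assert rec.truth["n_programmed_events"] == 0

    def test_onset_rule_controls_phonating_cells(self):
        records = gk.generate_grid(gk.GridConfig(seed=0))
        for cond, rec in records.items():
            assert (rec is not None) == gk.default_onset_rule(*cond)


class TestAcoustic:
    def test_constant_f0_dominates_spectrum(self, clean_tone):
        ac = gk.generate_acoustic(clean_tone, noise_sd=0.001)
        spec = np.abs(np.fft.rfft(ac.samples))
        freqs = np.fft.rfftfreq(len(ac.samples), 1.0 / ac.sample_rate)
        band = freqs < 2000
        peak_f = freqs[band][np.argmax(spec[band])]
        assert abs(peak_f - 300.0) <= freqs[1]  # one FFT bin

    def test_flat_gaw_gives_pure_noise(self):
        rec = gk.GAWRecord(np.full(3000, 100.0), np.full(3000, 50.0),
                           np.full(3000, 50.0))
        ac = gk.generate_acoustic(rec, noise_sd=0.01, seed=4)
        assert abs(np.std(ac.samples) - 0.01) < 0.002
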