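import numpy as np
import pytest

import gawkit as gk


@pytest.fixture(scope="session")
def grid_results():
    """A full analyzed 320-cell stimulation grid (shared; ~15 s to build)."""
    records = gk.generate_grid(gk.GridConfig(seed=1))
    return records, gk.analyze_grid(records)


@pytest.fixture
def clean_tone():
    """Noiseless constant-amplitude 300 Hz recording, 1 s at 3000 fps."""
    cfg = gk.SynthConfig(
        duration=1.0,
        f0_schedule=((0.0, 300.0),),
        amplitude_start=1000.0,
        amplitude_end=1000.0,
        jitter_sd=0.0,
        shimmer_sd=0.0,
        noise_sd=0.0,
        baseline=0.0,
    )
    return gk.generate_gaw(cfg)


def brute_local_maxima(x):
    """Interior strict local maxima (tie-free series assumed)."""
    return [i for i in range(1, len(x) - 1) if x[i - 1] < x[i] > x[i + 1]]


def brute_prominence(x, p):
    """Textbook prominence: min toward the nearest higher point on each side,
    the higher of the two minima subtracted from the peak."""
    left_min = x[p]
    i = p - 1
    while i >= 0 and x[i] <= x[p]:
        left_min = min(left_min, x[i])
        i -= 1
    right_min = x[p]
    i = p + 1
    while i < len(x) and x[i] <= x[p]:
        right_min = min(right_min, x[i])
        i += 1
    return x[p] - max(left_min, right_min)


def brute_detect_peaks(x, min_distance=3, prominence_fraction=0.05,
                       window_ms=12.5, frame_rate=3000.0):
    """From-scratch peak detector implementing the same contract as
    gawkit.detect_peaks (independent of scipy)."""
    maxima = brute_local_maxima(x)
    if not maxima:
        return []
    w = int(np.floor(window_ms * frame_rate / 1000.0 + 0.5))
    mdr = max(
        x[m] - min(x[max(0, m - w): m + w + 1]) for m in maxima
    )
    prominent = [m for m in maxima
                 if brute_prominence(x, m) + 1e-9 >= prominence_fraction * mdr]
    kept = []
    for m in sorted(prominent, key=lambda i: (-x[i], i)):
        if all(abs(m - k) >= min_distance for k in kept):
            kept.append(m)
    return sorted(kept)
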