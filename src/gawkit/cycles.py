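"""Maximum-based oscillation cycle detection on the total GAW.

A cycle runs from one glottal-area maximum to the next; its internal minimum
splits it into a closing and an opening part.  Peaks are local maxima whose
prominence reaches 5% of the recording's *maximum dynamic range* (the largest
peak-to-nearby-trough excursion, troughs searched within +-12.5 ms), thinned
so no two retained peaks are closer than 3 frames (1 ms at 3000 frames/s).
The prominence floor is relative so that recordings of very different
amplitude — and the amplitude growth along the airflow ramp — are treated
uniformly.

Cycles overlapping damaged video frames are excluded, and cycles whose length
is extreme against the local median length (default: outside [0.5x, 2.0x]
within an 11-cycle window) are flagged as detection outliers.  The bounds are
deliberately loose enough that a genuine octave drop (cycle length doubling
at a mode change) is never flagged: a 2.0x ratio is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_prominences

__all__ = [
    "PeakConfig",
    "Cycle",
    "max_dynamic_range",
    "detect_peaks",
    "build_cycles",
    "exclude_damaged",
    "remove_outlier_cycles",
    "cycle_table",
]

#: Absolute slack on threshold comparisons; the 5% fraction is not exactly
#: representable in binary and boundary cases are inclusive-keep.
_EPS = 1e-9


@dataclass(frozen=True)
class PeakConfig:
    """Peak-detection constants (defaults are the reference-analysis values)."""

    min_peak_distance_frames: int = 3
    prominence_fraction: float = 0.05
    dynamic_range_window_ms: float = 12.5

    def __post_init__(self) -> None:
        if (
            self.min_peak_distance_frames <= 0
            or self.prominence_fraction <= 0
            or self.dynamic_range_window_ms <= 0
        ):
            raise ValueError("all PeakConfig fields must be positive")


@dataclass
class Cycle:
    """One maximum-to-maximum cycle; ``end_frame`` is shared with the next
    cycle (half-open interval ``[start_frame, end_frame)``)."""

    start_frame: int
    end_frame: int
    min_frame: int
    valid: bool = True
    exclusion_reason: str | None = None

    @property
    def length_frames(self) -> int:
        return self.end_frame - self.start_frame

    def overlaps(self, frame: int) -> bool:
        return self.start_frame <= frame < self.end_frame


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def max_dynamic_range(
    gaw: np.ndarray, window_ms: float = 12.5, frame_rate: float = 3000.0
) -> float:
    """Largest (peak minus nearby trough) excursion of the series.

    For every interior local maximum the minimum within +-``window_ms`` is
    subtracted; the largest difference over all maxima is returned.  At
    3000 frames/s the 12.5 ms window is +-38 frames (round-half-up).
    Raises ``ValueError`` on a series with no interior local maximum.
    """
    x = np.asarray(gaw, dtype=float)
    peaks, _ = find_peaks(x)
    if len(peaks) == 0:
        raise ValueError("series has no interior local maximum (flat or monotone)")
    w = _round_half_up(window_ms * frame_rate / 1000.0)
    best = -np.inf
    for m in peaks:
        lo = max(0, m - w)
        hi = min(len(x), m + w + 1)
        best = max(best, x[m] - float(np.min(x[lo:hi])))
    return float(best)


def _greedy_distance_filter(
    peaks: np.ndarray, heights: np.ndarray, min_distance: int
) -> np.ndarray:
    """Keep peaks so no two retained ones are closer than ``min_distance``.

    Peaks are processed in decreasing height; exact height ties go to the
    earlier index.  Separation exactly equal to ``min_distance`` is kept.
    """
    order = sorted(range(len(peaks)), key=lambda i: (-heights[i], peaks[i]))
    kept: list[int] = []
    for i in order:
        if all(abs(peaks[i] - peaks[j]) >= min_distance for j in kept):
            kept.append(i)
    return np.array(sorted(peaks[i] for i in kept), dtype=int)


def detect_peaks(gaw: np.ndarray, cfg: PeakConfig = PeakConfig(),
                 frame_rate: float = 3000.0) -> np.ndarray:
    """Detect cycle-anchoring maxima of the total GAW.

    Interior local maxima with prominence >= ``prominence_fraction`` x the
    recording's maximum dynamic range are thinned with the greedy minimum
    distance filter.  Returns a sorted index array (possibly empty).
    """
    x = np.asarray(gaw, dtype=float)
    if len(x) == 0:
        return np.array([], dtype=int)
    candidates, _ = find_peaks(x)
    if len(candidates) == 0:
        return np.array([], dtype=int)
    threshold = cfg.prominence_fraction * max_dynamic_range(
        x, cfg.dynamic_range_window_ms, frame_rate
    )
    prom = peak_prominences(x, candidates)[0]
    keep = candidates[prom + _EPS >= threshold]
    if len(keep) == 0:
        return np.array([], dtype=int)
    return _greedy_distance_filter(keep, x[keep], cfg.min_peak_distance_frames)


def build_cycles(peaks: Sequence[int], gaw: np.ndarray) -> list[Cycle]:
    """One cycle per consecutive peak pair; fewer than 2 peaks gives none.

    The internal minimum is the argmin strictly between the two peaks
    (earliest index on exact ties).
    """
    x = np.asarray(gaw, dtype=float)
    peaks = np.asarray(peaks, dtype=int)
    cycles: list[Cycle] = []
    for a, b in zip(peaks, peaks[1:]):
        interior = x[a + 1 : b]
        min_frame = a + 1 + int(np.argmin(interior))
        cycles.append(Cycle(start_frame=int(a), end_frame=int(b), min_frame=min_frame))
    return cycles


def exclude_damaged(cycles: Sequence[Cycle], damaged_mask: np.ndarray) -> list[Cycle]:
    """Flag every cycle whose ``[start, end)`` span touches a damaged frame."""
    mask = np.asarray(damaged_mask, dtype=bool)
    out = []
    for c in cycles:
        if mask[c.start_frame : c.end_frame].any():
            out.append(replace(c, valid=False, exclusion_reason="damaged"))
        else:
            out.append(replace(c))
    return out


def remove_outlier_cycles(
    cycles: Sequence[Cycle],
    window: int = 11,
    low: float = 0.5,
    high: float = 2.0,
) -> list[Cycle]:
    """Flag cycles whose length is extreme against the local median length.

    The median is taken over a ``window``-cycle window centered on each cycle
    (shrunk at the boundaries) using the *original* lengths of all cycles in
    a single pass.  A cycle is an outlier iff its length is strictly below
    ``low`` x median or strictly above ``high`` x median, so a legitimate
    octave drop (ratio exactly 2) survives.  Cycles already excluded keep
    their original reason.
    """
    if not cycles:
        return []
    lengths = np.array([c.length_frames for c in cycles], dtype=float)
    half = window // 2
    out = []
    for i, c in enumerate(cycles):
        lo = max(0, i - half)
        hi = min(len(cycles), i + half + 1)
        med = float(np.median(lengths[lo:hi]))
        is_outlier = lengths[i] < low * med - _EPS or lengths[i] > high * med + _EPS
        if is_outlier and c.valid:
            out.append(replace(c, valid=False, exclusion_reason="outlier"))
        else:
            out.append(replace(c))
    return out


def cycle_table(cycles: Sequence[Cycle], recording_id: str = "rec") -> pd.DataFrame:
    """Cycle list as a tidy table (one row per cycle)."""
    return pd.DataFrame(
        {
            "recording_id": recording_id,
            "cycle_index": np.arange(len(cycles)),
            "start_frame": [c.start_frame for c in cycles],
            "min_frame": [c.min_frame for c in cycles],
            "end_frame": [c.end_frame for c in cycles],
            "length_frames": [c.length_frames for c in cycles],
            "valid": [c.valid for c in cycles],
            "exclusion_reason": [c.exclusion_reason for c in cycles],
        }
    )
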