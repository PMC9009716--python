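"""The seven cycle-based vibratory parameters.

Computed per valid cycle on the total GAW and its left/right partials:

========  =======  ====================================================
LF0       Hz       frame_rate / cycle length (local fundamental freq.)
DR        pixel^2  max - min of the total GAW over the cycle
PHA       a.u.     normalized left-right timing offset of the partial
                   maxima; positive = left-side phase lead
AP        a.u.     min/max ratio of neighboring cycles' dynamic ranges
TP        a.u.     min/max ratio of neighboring cycles' lengths
OD        ms       opening time: cycle minimum to cycle end
CD        ms       closing time: cycle start (maximum) to cycle minimum
========  =======  ====================================================

AP and TP equal 1 for a perfectly periodic signal and fall with shimmer and
jitter respectively; they are only defined across directly consecutive valid
cycles (pairs broken by an excluded cycle yield no value).  OD + CD equals
the cycle duration exactly by frame arithmetic.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .cycles import Cycle
from .io_preprocess import GAWRecord

__all__ = [
    "compute_lf0",
    "compute_dr",
    "compute_pha",
    "compute_ap",
    "compute_tp",
    "compute_od_cd",
    "parameter_table",
]


def compute_lf0(cycle: Cycle, frame_rate: float) -> float:
    """Local fundamental frequency: inverse cycle duration, in Hz."""
    return frame_rate / cycle.length_frames


def compute_dr(cycle: Cycle, gaw: np.ndarray) -> float:
    """Dynamic range: max - min of the total GAW over ``[start, end]``."""
    seg = np.asarray(gaw, dtype=float)[cycle.start_frame : cycle.end_frame + 1]
    return float(np.max(seg) - np.min(seg))


def compute_pha(cycle: Cycle, left: np.ndarray, right: np.ndarray) -> float:
    """Left-right phase asymmetry, in cycles, wrapped into [-0.5, 0.5].

    ``(t_max_right - t_max_left) / length``: the left and right partial-GAW
    argmax within ``[start, end)`` (earliest index on ties).  Positive values
    mean the left side peaks first (left phase lead).
    """
    s, e = cycle.start_frame, cycle.end_frame
    t_left = int(np.argmax(np.asarray(left, dtype=float)[s:e]))
    t_right = int(np.argmax(np.asarray(right, dtype=float)[s:e]))
    pha = (t_right - t_left) / cycle.length_frames
    # wrap: a lag of +0.8 cycles is the same timing as -0.2
    if pha > 0.5:
        pha -= 1.0
    elif pha < -0.5:
        pha += 1.0
    return pha


def compute_ap(dr_i: float, dr_next: float) -> float:
    """Amplitude periodicity of a neighboring-cycle pair: min/max of the two
    dynamic ranges (1 when equal; defined as 1 when both are zero)."""
    hi = max(dr_i, dr_next)
    if hi == 0.0:
        return 1.0
    return min(dr_i, dr_next) / hi


def compute_tp(len_i: int, len_next: int) -> float:
    """Time periodicity of a neighboring-cycle pair: min/max of the two
    lengths."""
    return min(len_i, len_next) / max(len_i, len_next)


def compute_od_cd(cycle: Cycle, frame_rate: float) -> tuple[float, float]:
    """(opening, closing) durations in ms.

    CD runs from the cycle-start maximum to the minimum, OD from the minimum
    to the cycle end; they sum to the cycle duration exactly.
    """
    ms = 1000.0 / frame_rate
    cd = (cycle.min_frame - cycle.start_frame) * ms
    od = (cycle.end_frame - cycle.min_frame) * ms
    return od, cd


def parameter_table(cycles: Sequence[Cycle], record: GAWRecord) -> pd.DataFrame:
    """Per-cycle parameter table for one recording.

    One row per detected cycle (valid or not); parameters are NaN where a
    cycle is excluded, and AP/TP are NaN additionally where the next cycle
    is missing or excluded.  ``time_s`` is the cycle-start time from segment
    start.
    """
    fr = record.frame_rate
    n = len(cycles)
    cols: dict[str, list] = {k: [] for k in
                             ("lf0", "dr", "pha", "ap", "tp", "od", "cd")}
    for i, c in enumerate(cycles):
        if not c.valid:
            for k in cols:
                cols[k].append(np.nan)
            continue
        od, cd = compute_od_cd(c, fr)
        cols["lf0"].append(compute_lf0(c, fr))
        cols["dr"].append(compute_dr(c, record.total))
        cols["pha"].append(compute_pha(c, record.left, record.right))
        cols["od"].append(od)
        cols["cd"].append(cd)
        nxt = cycles[i + 1] if i + 1 < n else None
        if nxt is not None and nxt.valid:
            cols["ap"].append(
                compute_ap(compute_dr(c, record.total), compute_dr(nxt, record.total))
            )
            cols["tp"].append(compute_tp(c.length_frames, nxt.length_frames))
        else:
            cols["ap"].append(np.nan)
            cols["tp"].append(np.nan)
    return pd.DataFrame(
        {
            "recording_id": record.recording_id,
            "cycle_index": np.arange(n),
            "time_s": [c.start_frame / fr for c in cycles],
            "valid": [c.valid for c in cycles],
            **cols,
        }
    )
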