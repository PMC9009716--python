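"""Detection and characterization of spontaneous vibratory mode changes.

A mode change appears as an abrupt, *sustained* jump or drop of the local
fundamental frequency (LF0).  Detection works on the sequence of per-cycle
LF0 values of the valid cycles:

1. the sequence is smoothed with a ten-point centered moving mean (a moving
   median is available as an option) and the first and last five smoothed
   values are discarded;
2. a position is a change candidate if the smoothed LF0 moves by at least
   50 Hz within ten cycles and stays at least 50 Hz away, on the same side,
   for at least five consecutive cycles;
3. overlapping candidates are merged into one event anchored at the point of
   steepest smoothed change, and events too close to either end of the
   signal (where onset/offset transients masquerade as changes) are dropped.

Each event is characterized by the medians of LF0 and dynamic range over up
to 10 valid cycles immediately before and after it, and by the airflow at
the event time read off the linear flow ramp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_preprocess import GAWRecord

__all__ = [
    "DetectorConfig",
    "ModeChangeEvent",
    "smooth_lf0",
    "detect_mode_changes",
    "characterize_event",
    "events_table",
]

_EPS = 1e-9


@dataclass(frozen=True)
class DetectorConfig:
    """Mode-change detector constants (defaults are the reference values).

    ``smooth_window`` cycles of centered moving mean; ``edge_exclude``
    smoothed values dropped at each end; a change of ``delta_threshold`` Hz
    within ``span_window`` cycles sustained for ``sustain_cycles`` cycles is
    an event; events within ``boundary_guard`` cycles of either end are
    discarded.  ``method`` selects ``"mean"`` or ``"median"`` smoothing.
    """

    smooth_window: int = 10
    edge_exclude: int = 5
    delta_threshold: float = 50.0
    span_window: int = 10
    sustain_cycles: int = 5
    boundary_guard: int = 10
    method: str = "mean"

    def __post_init__(self) -> None:
        for name in ("smooth_window", "edge_exclude", "span_window",
                     "sustain_cycles", "boundary_guard"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if self.delta_threshold <= 0:
            raise ValueError("delta_threshold must be positive")
        if self.method not in ("mean", "median"):
            raise ValueError("method must be 'mean' or 'median'")


@dataclass
class ModeChangeEvent:
    """One detected sustained LF0 jump (``up``) or drop (``down``)."""

    event_cycle: int
    event_time: float
    direction: str
    lf0_before: float = np.nan
    lf0_after: float = np.nan
    dr_before: float = np.nan
    dr_after: float = np.nan
    flow_at_event: float = np.nan
    recording_id: str = "rec"


def smooth_lf0(lf0: pd.Series, cfg: DetectorConfig = DetectorConfig()) -> pd.Series:
    """Smooth a per-cycle LF0 series and drop the edge values.

    ``lf0`` must be indexed by cycle index (valid cycles only); the result
    keeps that index so smoothed positions map back to cycles.  The window
    is centered covering ``[i - w//2, i + w//2 - 1]`` for even ``w`` (the
    usual moving-mean convention) and shrinks at the boundaries.  Raises
    ``ValueError`` when fewer than ``smooth_window + 2 * edge_exclude``
    values are available.
    """
    v = np.asarray(lf0.values, dtype=float)
    n = len(v)
    if n < cfg.smooth_window + 2 * cfg.edge_exclude:
        raise ValueError(
            f"LF0 sequence of {n} cycles is too short to smooth "
            f"(need {cfg.smooth_window + 2 * cfg.edge_exclude})"
        )
    w = cfg.smooth_window
    before = w // 2
    after = w - before - 1
    agg = np.mean if cfg.method == "mean" else np.median
    sm = np.array(
        [agg(v[max(0, i - before) : min(n, i + after + 1)]) for i in range(n)]
    )
    e = cfg.edge_exclude
    return pd.Series(sm[e : n - e], index=lf0.index[e : n - e])


def detect_mode_changes(
    smoothed: pd.Series, cfg: DetectorConfig = DetectorConfig()
) -> list[ModeChangeEvent]:
    """Find sustained LF0 shifts in a smoothed per-cycle LF0 series.

    Position ``i`` is a candidate if, for some ``j`` with
    ``0 < j - i <= span_window``, the smoothed LF0 moved by at least
    ``delta_threshold`` Hz and at least ``sustain_cycles`` consecutive values
    from ``j`` onward stay that far away on the same side of ``smoothed[i]``.
    Maximal runs of nearby same-direction candidates are merged into one
    event anchored at the steepest single-step change; events within
    ``boundary_guard`` positions of either end are discarded.  Events carry
    cycle index and direction only; see :func:`characterize_event`.
    """
    v = np.asarray(smoothed.values, dtype=float)
    n = len(v)
    delta = cfg.delta_threshold - _EPS
    candidates: list[tuple[int, int]] = []  # (position, sign)
    for i in range(n):
        found = 0
        for j in range(i + 1, min(i + cfg.span_window, n - 1) + 1):
            d = v[j] - v[i]
            if abs(d) < delta:
                continue
            s = 1 if d > 0 else -1
            if j + cfg.sustain_cycles > n:
                continue
            run = v[j : j + cfg.sustain_cycles] - v[i]
            if np.all(s * run >= delta):
                found = s
                break
        if found:
            candidates.append((i, found))

    events: list[ModeChangeEvent] = []
    k = 0
    while k < len(candidates):
        pos0, sign = candidates[k]
        m = k
        while (
            m + 1 < len(candidates)
            and candidates[m + 1][1] == sign
            and candidates[m + 1][0] - candidates[m][0] <= cfg.span_window
        ):
            m += 1
        run_end = candidates[m][0]
        lo = pos0
        hi = min(run_end + cfg.span_window, n - 2)
        diffs = sign * (v[lo + 1 : hi + 2] - v[lo : hi + 1])
        anchor = lo + int(np.argmax(diffs)) + 1  # first position of new regime
        if cfg.boundary_guard <= anchor < n - cfg.boundary_guard:
            events.append(
                ModeChangeEvent(
                    event_cycle=int(smoothed.index[anchor]),
                    event_time=np.nan,
                    direction="up" if sign > 0 else "down",
                )
            )
        k = m + 1
    return events


def characterize_event(
    event: ModeChangeEvent,
    params: pd.DataFrame,
    record: GAWRecord,
    n_context: int = 10,
) -> ModeChangeEvent:
    """Fill an event's before/after medians and airflow.

    ``lf0_before`` / ``dr_before`` are medians over the up-to-``n_context``
    valid cycles strictly before the event cycle, and symmetrically after
    (the event cycle itself is attributed to the new regime's side only
    through the ``after`` window start).  ``flow_at_event`` evaluates the
    linear ramp at onset time plus event time.  Sides with no valid cycle
    leave their medians NaN.
    """
    valid = params[params["valid"]]
    before = valid[valid["cycle_index"] < event.event_cycle].tail(n_context)
    after = valid[valid["cycle_index"] > event.event_cycle].head(n_context)
    event.lf0_before = float(before["lf0"].median()) if len(before) else np.nan
    event.dr_before = float(before["dr"].median()) if len(before) else np.nan
    event.lf0_after = float(after["lf0"].median()) if len(after) else np.nan
    event.dr_after = float(after["dr"].median()) if len(after) else np.nan

    row = params[params["cycle_index"] == event.event_cycle]
    event.event_time = float(row["time_s"].iloc[0]) if len(row) else np.nan
    t_stim = record.onset_frame / record.frame_rate + event.event_time
    event.flow_at_event = record.flow_ramp.flow_at(t_stim)
    event.recording_id = record.recording_id
    return event


def events_table(events: Sequence[ModeChangeEvent],
                 record: GAWRecord | None = None) -> pd.DataFrame:
    """Event list as a tidy table (one row per event)."""
    rows = []
    for ev in events:
        row = {
            "recording_id": ev.recording_id,
            "event_cycle": ev.event_cycle,
            "event_time_s": ev.event_time,
            "direction": ev.direction,
            "lf0_before": ev.lf0_before,
            "lf0_after": ev.lf0_after,
            "dr_before": ev.dr_before,
            "dr_after": ev.dr_after,
            "flow_at_event": ev.flow_at_event,
        }
        if record is not None:
            row.update(
                sln=record.condition.sln,
                rln_left=record.condition.rln_left,
                rln_right=record.condition.rln_right,
            )
        rows.append(row)
    cols = ["recording_id", "event_cycle", "event_time_s", "direction",
            "lf0_before", "lf0_after", "dr_before", "dr_after", "flow_at_event"]
    if record is not None:
        cols = cols[:1] + ["sln", "rln_left", "rln_right"] + cols[1:]
    return pd.DataFrame(rows, columns=cols)
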