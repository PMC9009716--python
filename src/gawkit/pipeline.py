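"""End-to-end analysis of recordings and recording grids.

``analyze_recording`` chains the full path: trim -> inclusion filter ->
peak/cycle detection -> damaged/outlier exclusion -> parameter table ->
LF0 smoothing -> mode-change detection -> event characterization.
``analyze_grid`` maps it over a condition grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cycles as _cycles
from .cycles import Cycle, PeakConfig
from .io_preprocess import Condition, GAWRecord, passes_inclusion, trim_onset_offset
from .modechange import (
    DetectorConfig,
    ModeChangeEvent,
    characterize_event,
    detect_mode_changes,
    events_table,
    smooth_lf0,
)
from .params import parameter_table

__all__ = ["AnalysisResult", "analyze_recording", "analyze_grid", "grid_events_table"]

logger = logging.getLogger("gawkit")


@dataclass
class AnalysisResult:
    """Everything computed for one recording."""

    record: GAWRecord
    included: bool
    skip_reason: str | None = None
    cycles: list[Cycle] = field(default_factory=list)
    params: pd.DataFrame | None = None
    lf0_smooth: pd.Series | None = None
    events: list[ModeChangeEvent] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return len(self.events)


def analyze_recording(
    record: GAWRecord,
    peak_cfg: PeakConfig = PeakConfig(),
    detector_cfg: DetectorConfig = DetectorConfig(),
    trim: bool = True,
    n_context: int = 10,
) -> AnalysisResult:
    """Run the full cycle/parameter/mode-change analysis on one recording.

    Recordings failing the inclusion filter, or yielding too few valid
    cycles to smooth, are returned with ``included=False`` /
    empty event lists and a ``skip_reason``; nothing raises on ordinary
    short or quiet signals.
    """
    if trim:
        try:
            record = trim_onset_offset(record)
        except ValueError as exc:
            logger.info("excluded %s: %s", record.recording_id, exc)
            return AnalysisResult(record, included=False, skip_reason=str(exc))
    if not passes_inclusion(record):
        reason = (
            f"below minimum continuous phonation ({record.n_frames} frames)"
        )
        logger.info("excluded %s: %s", record.recording_id, reason)
        return AnalysisResult(record, included=False, skip_reason=reason)

    try:
        peaks = _cycles.detect_peaks(record.total, peak_cfg, record.frame_rate)
    except ValueError as exc:  # flat signal: no usable oscillation
        logger.info("excluded %s: %s", record.recording_id, exc)
        return AnalysisResult(record, included=False, skip_reason=str(exc))
    cyc = _cycles.build_cycles(peaks, record.total)
    cyc = _cycles.exclude_damaged(cyc, record.damaged_mask)
    cyc = _cycles.remove_outlier_cycles(cyc)
    params = parameter_table(cyc, record)
    result = AnalysisResult(record, included=True, cycles=cyc, params=params)

    valid = params[params["valid"]]
    lf0 = pd.Series(valid["lf0"].values, index=valid["cycle_index"].values)
    try:
        smoothed = smooth_lf0(lf0, detector_cfg)
    except ValueError as exc:
        logger.info("no detection for %s: %s", record.recording_id, exc)
        result.skip_reason = str(exc)
        return result
    result.lf0_smooth = smoothed
    events = detect_mode_changes(smoothed, detector_cfg)
    result.events = [
        characterize_event(ev, params, record, n_context) for ev in events
    ]
    for ev in result.events:
        logger.info(
            "%s: mode change (%s) at cycle %d, t=%.3f s, flow %.0f mL/s",
            record.recording_id, ev.direction, ev.event_cycle,
            ev.event_time, ev.flow_at_event,
        )
    return result


def analyze_grid(
    records: Mapping[Condition, GAWRecord | None],
    peak_cfg: PeakConfig = PeakConfig(),
    detector_cfg: DetectorConfig = DetectorConfig(),
) -> dict[Condition, AnalysisResult | None]:
    """Analyze every phonating cell of a condition grid (``None`` passes
    through)."""
    out: dict[Condition, AnalysisResult | None] = {}
    for cond, rec in records.items():
        out[cond] = None if rec is None else analyze_recording(
            rec, peak_cfg, detector_cfg
        )
    return out


def grid_events_table(
    results: Mapping[Condition, AnalysisResult | None]
) -> pd.DataFrame:
    """All detected events of a grid as one table with condition columns."""
    frames = [
        events_table(res.events, res.record)
        for res in results.values()
        if res is not None and res.events
    ]
    if not frames:
        return events_table([], GAWRecord(np.zeros(3), np.zeros(3), np.zeros(3)))
    return pd.concat(frames, ignore_index=True)
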