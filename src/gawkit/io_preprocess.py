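"""Reading, writing and pre-filtering of glottal area waveform (GAW) recordings.

A recording is one phonation segment extracted from a high-speed video of the
vibrating vocal folds: the total glottal area per frame plus the left and right
hemiglottal partial areas split at the glottal midline, sampled at the video
frame rate (3000 frames/s in the reference setup).  Each recording carries the
neuromuscular condition that produced it (superior laryngeal nerve level 0-4,
left/right recurrent laryngeal nerve levels 0-7), the airflow ramp driving
phonation, and a mask of damaged video frames.

Two pre-filters are applied before any cycle analysis:

* the first and last 10 ms of the segment are discarded (onset/offset
  transients are not analysed), and
* segments shorter than 0.25 s of continuous phonation after trimming are
  excluded altogether.

Frame indices are 0-based and all intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "FlowRamp",
    "GAWRecord",
    "AcousticRecord",
    "read_gaw",
    "write_gaw",
    "trim_onset_offset",
    "passes_inclusion",
    "TRIM_SECONDS",
    "MIN_PHONATION_SECONDS",
]

#: Duration removed from each end of a phonation segment (10 ms = 30 frames
#: at 3000 frames/s).
TRIM_SECONDS = 0.010

#: Minimum continuous phonation required for a recording to enter analysis
#: (0.25 s = 750 frames at 3000 frames/s).
MIN_PHONATION_SECONDS = 0.25

GAW_COLUMNS = ("frame_index", "total_area", "left_area", "right_area", "damaged")


class Condition(NamedTuple):
    """Neuromuscular stimulation condition of one recording."""

    sln: int = 0
    rln_left: int = 0
    rln_right: int = 0


class FlowRamp(NamedTuple):
    """Linear airflow ramp driving phonation (mL/s over the stimulation epoch)."""

    flow_start: float = 300.0
    flow_end: float = 1400.0
    ramp_duration: float = 1.5

    def flow_at(self, t_stim: float) -> float:
        """Airflow (mL/s) at time ``t_stim`` seconds after stimulation start.

        The ramp is linear and saturates at ``flow_end`` once the ramp
        duration is exceeded.
        """
        frac = min(max(t_stim, 0.0) / self.ramp_duration, 1.0)
        return self.flow_start + (self.flow_end - self.flow_start) * frac


@dataclass
class GAWRecord:
    """One glottal-area-waveform recording.

    Areas are in pixel^2 (nominal; the analysis is unit-agnostic).
    ``onset_frame`` locates the first frame of this segment within the
    stimulation epoch, so that event times can be mapped onto the airflow
    ramp.  ``truth`` optionally carries the ground-truth generator settings
    of a synthetic recording; it is round-tripped but never consulted by the
    analysis.
    """

    total: np.ndarray
    left: np.ndarray
    right: np.ndarray
    frame_rate: float = 3000.0
    damaged_mask: np.ndarray | None = None
    condition: Condition = Condition()
    flow_ramp: FlowRamp = FlowRamp()
    onset_frame: int = 0
    recording_id: str = "rec"
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.total = np.asarray(self.total, dtype=float)
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.damaged_mask is None:
            self.damaged_mask = np.zeros(self.total.shape, dtype=bool)
        else:
            self.damaged_mask = np.asarray(self.damaged_mask, dtype=bool)
        if not isinstance(self.condition, Condition):
            self.condition = Condition(*self.condition)
        if not isinstance(self.flow_ramp, FlowRamp):
            self.flow_ramp = FlowRamp(*self.flow_ramp)
        self.validate()

    @property
    def n_frames(self) -> int:
        return len(self.total)

    @property
    def duration(self) -> float:
        """Segment duration in seconds."""
        return self.n_frames / self.frame_rate

    def times(self) -> np.ndarray:
        """Time of each frame in seconds from segment start."""
        return np.arange(self.n_frames) / self.frame_rate

    def validate(self) -> None:
        n = self.n_frames
        for name in ("left", "right", "damaged_mask"):
            if len(getattr(self, name)) != n:
                raise ValueError(
                    f"{self.recording_id}: column '{name}' has length "
                    f"{len(getattr(self, name))}, expected {n}"
                )
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        ok = self.damaged_mask.copy()
        for arr in (self.total, self.left, self.right):
            if np.any(arr[~ok] < 0):
                raise ValueError("negative area at a non-damaged frame")
        if self.flow_ramp.flow_end < self.flow_ramp.flow_start:
            raise ValueError("flow_end must be >= flow_start")

    def slice_frames(self, start: int, stop: int) -> "GAWRecord":
        """Return a copy restricted to frames ``[start, stop)``."""
        return dataclasses.replace(
            self,
            total=self.total[start:stop],
            left=self.left[start:stop],
            right=self.right[start:stop],
            damaged_mask=self.damaged_mask[start:stop],
            onset_frame=self.onset_frame + start,
        )


@dataclass
class AcousticRecord:
    """Synchronous acoustic channel (pressure-like, typically 50 kHz)."""

    samples: np.ndarray
    sample_rate: float = 50000.0
    recording_id: str = "rec"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_gaw(record: GAWRecord, path: str | Path) -> Path:
    """Write a recording as CSV plus a JSON metadata sidecar.

    The CSV holds ``frame_index, total_area, left_area, right_area, damaged``;
    the sidecar holds frame rate, condition, flow ramp, onset frame and (for
    synthetic data) the generator ground truth.  ``read_gaw`` inverts this
    losslessly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "frame_index": np.arange(record.n_frames),
            "total_area": record.total,
            "left_area": record.left,
            "right_area": record.right,
            "damaged": record.damaged_mask.astype(int),
        }
    )
    df.to_csv(path, index=False)
    meta = {
        "recording_id": record.recording_id,
        "frame_rate": record.frame_rate,
        "condition": {
            "sln": record.condition.sln,
            "rln_left": record.condition.rln_left,
            "rln_right": record.condition.rln_right,
        },
        "flow_ramp": {
            "flow_start": record.flow_ramp.flow_start,
            "flow_end": record.flow_ramp.flow_end,
            "ramp_duration": record.flow_ramp.ramp_duration,
        },
        "onset_frame": int(record.onset_frame),
    }
    if record.truth is not None:
        meta["truth"] = record.truth
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_gaw(path: str | Path) -> GAWRecord:
    """Read a recording written by :func:`write_gaw`.

    Raises ``ValueError`` naming the offending column (and first bad row) on
    missing columns or ragged data.
    """
    path = Path(path)
    # round_trip parsing keeps write -> read bit-exact on float areas
    df = pd.read_csv(path, float_precision="round_trip")
    for col in GAW_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column '{col}'")
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValueError(
                f"{path.name}: column '{col}' has a missing value at row "
                f"{int(bad[0])} (unequal column lengths?)"
            )
    meta = json.loads(_sidecar_path(path).read_text())
    cond = meta.get("condition", {})
    ramp = meta.get("flow_ramp", {})
    return GAWRecord(
        total=df["total_area"].to_numpy(float),
        left=df["left_area"].to_numpy(float),
        right=df["right_area"].to_numpy(float),
        frame_rate=float(meta.get("frame_rate", 3000.0)),
        damaged_mask=df["damaged"].to_numpy() != 0,
        condition=Condition(
            int(cond.get("sln", 0)),
            int(cond.get("rln_left", 0)),
            int(cond.get("rln_right", 0)),
        ),
        flow_ramp=FlowRamp(
            float(ramp.get("flow_start", 300.0)),
            float(ramp.get("flow_end", 1400.0)),
            float(ramp.get("ramp_duration", 1.5)),
        ),
        onset_frame=int(meta.get("onset_frame", 0)),
        recording_id=str(meta.get("recording_id", path.stem)),
        truth=meta.get("truth"),
    )


def trim_frames(frame_rate: float, trim_seconds: float = TRIM_SECONDS) -> int:
    """Number of frames removed from each end (round-half-up)."""
    import math

    return int(math.floor(trim_seconds * frame_rate + 0.5))


def trim_onset_offset(
    record: GAWRecord, trim_seconds: float = TRIM_SECONDS
) -> GAWRecord:
    """Discard the first and last ``trim_seconds`` (default 10 ms) of a segment.

    At 3000 frames/s this removes 30 frames from each end.  ``onset_frame``
    is advanced by the leading trim so the segment stays anchored within the
    stimulation epoch.  Raises ``ValueError`` if nothing would remain.
    """
    k = trim_frames(record.frame_rate, trim_seconds)
    if record.n_frames <= 2 * k:
        raise ValueError(
            f"{record.recording_id}: {record.n_frames} frames is too short to "
            f"trim {k} frames from each end"
        )
    return record.slice_frames(k, record.n_frames - k)


def min_phonation_frames(
    frame_rate: float, min_seconds: float = MIN_PHONATION_SECONDS
) -> int:
    import math

    return int(math.floor(min_seconds * frame_rate + 0.5))


def passes_inclusion(
    record: GAWRecord, min_seconds: float = MIN_PHONATION_SECONDS
) -> bool:
    """True iff the (trimmed) segment reaches 0.25 s of continuous phonation.

    At 3000 frames/s the threshold is 750 frames.  Damaged frames do not
    break continuity; only the cycles overlapping them are excluded later.
    """
    return record.n_frames >= min_phonation_frames(record.frame_rate, min_seconds)
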