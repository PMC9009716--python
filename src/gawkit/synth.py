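"""Synthetic glottal-area-waveform generator.

The generator is phenomenological, not physical: it emits the signal
*structure* the downstream analysis assumes so that every stage can be tested
without laboratory data.  One recording is a concatenation of
maximum-to-maximum oscillation cycles:

* each cycle's nominal length is ``frame_rate / f0(t)`` with ``f0`` a
  piecewise-constant schedule; abrupt schedule steps ("mode changes", e.g.
  400 -> 200 Hz) are realized exactly at cycle boundaries;
* the pulse shape is a skewed raised cosine running from one maximum through
  the cycle minimum back to the next maximum, with the closing:opening split
  set by an OD:CD ratio (about 1 for a falsetto-like pulse, < 1 for a
  chest-like pulse whose closing duration dominates);
* the peak-to-trough amplitude follows a linear ramp (emulating linearly
  rising airflow) and may jump by a factor at the first transition;
* cycle lengths and amplitudes carry multiplicative Gaussian jitter/shimmer,
  optionally boosted in a window before each programmed transition to mimic
  the pre-event instability seen in real mode changes;
* left and right hemiglottal partials sum exactly to the total and are
  offset by a configurable phase lag;
* short runs of frames can be marked damaged (zeroed, as by camera dropout).

A full stimulation grid (5 SLN x 8 x 8 RLN levels = 320 cells) can be
generated with per-cell predicates deciding which cells phonate and which
contain a programmed mode change.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.signal import resample_poly

from .io_preprocess import AcousticRecord, Condition, FlowRamp, GAWRecord

__all__ = [
    "SynthConfig",
    "GridConfig",
    "generate_gaw",
    "generate_grid",
    "generate_acoustic",
    "default_onset_rule",
    "default_event_rule",
]

#: Cycles shorter than this are undetectable under the 3-frame minimum peak
#: distance rule and are rejected at config validation.
MIN_CYCLE_FRAMES = 4.0


@dataclass
class SynthConfig:
    """Parameters of one synthetic recording.

    ``f0_schedule`` is a list of ``(start_time_s, f0_hz)`` piecewise-constant
    segments.  ``transition_times`` marks which schedule breakpoints are
    programmed mode-change events; if ``None`` every breakpoint with a jump of
    at least 50 Hz counts.  ``perturbation_boost = (window_s, multiplier)``
    multiplies jitter and shimmer in the window before each transition.
    ``amplitude_jump`` multiplies the amplitude ramp from the first transition
    onward, emulating the sudden dynamic-range increase that accompanies a
    drop to a slower, wider oscillation mode.
    """

    frame_rate: float = 3000.0
    duration: float = 1.5
    f0_schedule: Sequence[tuple[float, float]] = ((0.0, 400.0),)
    transition_times: Sequence[float] | None = None
    amplitude_start: float = 800.0
    amplitude_end: float = 4000.0
    od_cd_ratio_pre: float = 1.0
    od_cd_ratio_post: float = 0.5
    amplitude_jump: float = 1.0
    jitter_sd: float = 0.02
    shimmer_sd: float = 0.02
    perturbation_boost: tuple[float, float] = (0.05, 3.0)
    phase_lag: float = 0.0
    left_right_split: float = 0.5
    noise_sd: float = 2.0
    damaged_runs: Sequence[tuple[int, int]] = ()
    baseline: float = 50.0
    seed: int = 0

    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    def resolved_transitions(self) -> list[float]:
        if self.transition_times is not None:
            return sorted(float(t) for t in self.transition_times)
        sched = sorted(self.f0_schedule)
        out = []
        for (_, f_prev), (t, f_next) in zip(sched, sched[1:]):
            if abs(f_next - f_prev) >= 50.0:
                out.append(float(t))
        return out

    def f0_at(self, t: float) -> float:
        """Scheduled fundamental frequency at time ``t`` (seconds)."""
        sched = sorted(self.f0_schedule)
        f0 = sched[0][1]
        for start, value in sched:
            if t >= start:
                f0 = value
        return f0

    def validate(self) -> None:
        n = self.duration * self.frame_rate
        if abs(n - round(n)) > 1e-6 or n <= 0:
            raise ValueError("duration x frame_rate must be a whole number of frames")
        if not self.f0_schedule:
            raise ValueError("f0_schedule must contain at least one segment")
        for _, f0 in self.f0_schedule:
            if not (0.0 < f0 < self.frame_rate / 2.0):
                raise ValueError(f"f0 {f0} Hz outside (0, frame_rate/2)")
            if self.frame_rate / f0 < MIN_CYCLE_FRAMES:
                raise ValueError(
                    f"f0 {f0} Hz implies cycles shorter than {MIN_CYCLE_FRAMES} "
                    "frames, undetectable under the 3-frame peak-distance rule"
                )
        if self.jitter_sd < 0 or self.shimmer_sd < 0:
            raise ValueError("jitter_sd and shimmer_sd must be >= 0")
        if not -0.5 <= self.phase_lag <= 0.5:
            raise ValueError("phase_lag must lie in [-0.5, 0.5]")
        if not 0.0 < self.left_right_split < 1.0:
            raise ValueError("left_right_split must lie in (0, 1)")
        if self.od_cd_ratio_pre <= 0 or self.od_cd_ratio_post <= 0:
            raise ValueError("OD:CD ratios must be positive")
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")
        nf = self.n_frames()
        for start, length in self.damaged_runs:
            if length > 20:
                raise ValueError("damaged runs must be at most 20 frames long")
            if start < 0 or start + length > nf:
                raise ValueError("damaged run outside the recording")


def _pulse(phase: np.ndarray, min_frac: float) -> np.ndarray:
    """Skewed raised-cosine pulse: 1 at phase 0 and 1, 0 at ``min_frac``.

    ``min_frac`` is the position of the cycle minimum as a fraction of the
    cycle, i.e. CD / (CD + OD) for maximum-anchored cycles.
    """
    phase = np.asarray(phase, dtype=float)
    out = np.empty_like(phase)
    closing = phase <= min_frac
    out[closing] = 0.5 * (1.0 + np.cos(np.pi * phase[closing] / min_frac))
    opening = ~closing
    out[opening] = 0.5 * (
        1.0 - np.cos(np.pi * (phase[opening] - min_frac) / (1.0 - min_frac))
    )
    return out


def generate_gaw(
    config: SynthConfig,
    *,
    condition: Condition = Condition(),
    flow_ramp: FlowRamp = FlowRamp(),
    onset_frame: int = 0,
    recording_id: str = "synthetic",
) -> GAWRecord:
    """Generate one synthetic GAW recording (reproducible from ``config.seed``)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_frames()
    left = np.zeros(n)
    right = np.zeros(n)
    transitions = config.resolved_transitions()
    first_transition = transitions[0] if transitions else np.inf
    boost_window, boost_mult = config.perturbation_boost
    amp_slope = (config.amplitude_end - config.amplitude_start) / config.duration

    cycle_starts: list[float] = []
    t = 0.0  # cycle start, in frames (fractional)
    while t < n - 1e-9:
        t_sec = t / config.frame_rate
        boost = 1.0
        for tr in transitions:
            if tr - boost_window <= t_sec < tr:
                boost = boost_mult
                break
        jit = rng.standard_normal() * config.jitter_sd * boost
        shim = rng.standard_normal() * config.shimmer_sd * boost
        f0 = config.f0_at(t_sec)
        length = (config.frame_rate / f0) * float(np.clip(1.0 + jit, 0.5, 2.0))
        amp = (config.amplitude_start + amp_slope * t_sec) * max(1.0 + shim, 0.0)
        if t_sec >= first_transition:
            amp *= config.amplitude_jump
        ratio = (
            config.od_cd_ratio_pre
            if t_sec < first_transition
            else config.od_cd_ratio_post
        )
        min_frac = 1.0 / (1.0 + ratio)

        k0 = int(np.ceil(t - 1e-9))
        k1 = min(int(np.ceil(t + length - 1e-9)), n)
        if k1 > k0:
            frames = np.arange(k0, k1)
            phase = (frames - t) / length
            lphase = np.mod(phase + config.phase_lag / 2.0, 1.0)
            rphase = np.mod(phase - config.phase_lag / 2.0, 1.0)
            left[frames] = config.left_right_split * amp * _pulse(lphase, min_frac)
            right[frames] = (1.0 - config.left_right_split) * amp * _pulse(
                rphase, min_frac
            )
        cycle_starts.append(t)
        t += length

    left += config.left_right_split * config.baseline
    right += (1.0 - config.left_right_split) * config.baseline
    if config.noise_sd > 0:
        side_sd = config.noise_sd / np.sqrt(2.0)
        left += rng.normal(0.0, side_sd, n)
        right += rng.normal(0.0, side_sd, n)
    np.clip(left, 0.0, None, out=left)
    np.clip(right, 0.0, None, out=right)

    mask = np.zeros(n, dtype=bool)
    for start, length in config.damaged_runs:
        mask[start : start + length] = True
    left[mask] = 0.0
    right[mask] = 0.0
    total = left + right

    truth = {
        "transition_times": transitions,
        "f0_schedule": [[float(a), float(b)] for a, b in sorted(config.f0_schedule)],
        "phase_lag": config.phase_lag,
        "amplitude_start": config.amplitude_start,
        "amplitude_end": config.amplitude_end,
        "od_cd_ratio_pre": config.od_cd_ratio_pre,
        "od_cd_ratio_post": config.od_cd_ratio_post,
        "n_programmed_events": len(transitions),
    }
    return GAWRecord(
        total=total,
        left=left,
        right=right,
        frame_rate=config.frame_rate,
        damaged_mask=mask,
        condition=condition,
        flow_ramp=flow_ramp,
        onset_frame=onset_frame,
        recording_id=recording_id,
        truth=truth,
    )


# --------------------------------------------------------------------------
# Stimulation grid
# --------------------------------------------------------------------------

def default_onset_rule(sln: int, rln_left: int, rln_right: int) -> bool:
    """Phonation-onset predicate for the default grid.

    Phonation requires enough total adduction; higher vocal-fold tension
    (SLN) raises the requirement, so fewer low-RLN cells phonate as SLN
    grows.  The exact predicate is a configuration choice, not a claim.
    """
    return rln_left + rln_right >= 2 + sln


def default_event_rule(sln: int, rln_left: int, rln_right: int) -> bool:
    """Mode-change predicate: events need tension (SLN > 0) plus strong,
    near-symmetric adduction."""
    return (
        sln >= 1
        and min(rln_left, rln_right) >= 5
        and abs(rln_left - rln_right) <= 1
    )


@dataclass
class GridConfig:
    """A 5 x 8 x 8 stimulation grid of synthetic recordings."""

    sln_levels: Sequence[int] = tuple(range(5))
    rln_levels: Sequence[int] = tuple(range(8))
    onset_rule: Callable[[int, int, int], bool] = default_onset_rule
    event_rule: Callable[[int, int, int], bool] = default_event_rule
    base: Mapping[str, object] = field(default_factory=dict)
    overrides: Mapping[tuple[int, int, int], Mapping[str, object]] = field(
        default_factory=dict
    )
    damage_fraction: float = 0.25
    seed: int = 0

    def conditions(self) -> list[Condition]:
        return [
            Condition(s, l, r)
            for s in self.sln_levels
            for l in self.rln_levels
            for r in self.rln_levels
        ]


def _cell_config(
    grid: GridConfig, cond: Condition, cell_seed: int, rng: np.random.Generator
) -> tuple[SynthConfig, float]:
    """Build the per-cell SynthConfig; returns (config, onset_time_s)."""
    sln, l, r = cond
    stim_duration = 1.5
    onset_time = 0.10 + 0.06 * sln + rng.uniform(-0.02, 0.02)
    frame_rate = 3000.0
    n = int(round((stim_duration - onset_time) * frame_rate))
    duration = n / frame_rate

    if sln == 0:
        f0_schedule = ((0.0, 220.0),)
    else:
        f0_pre = 350.0 + 17.0 * (sln - 1)
        if grid.event_rule(sln, l, r):
            t_event = float(rng.uniform(0.35, 0.70)) * duration
            f0_post = 205.0 + 15.0 * (sln - 1)
            f0_schedule = ((0.0, f0_pre), (t_event, f0_post))
        else:
            f0_schedule = ((0.0, f0_pre),)

    amp_end = 2500.0 + 125.0 * (l + r)
    damaged_runs: list[tuple[int, int]] = []
    if rng.random() < grid.damage_fraction:
        # keep damage clear of the programmed transition so ground-truth
        # event placement stays recoverable
        tr = [t for t, _ in f0_schedule[1:]]
        for _ in range(int(rng.integers(1, 3))):
            length = int(rng.integers(5, 20))
            for _attempt in range(20):
                start = int(rng.integers(100, max(101, n - length - 100)))
                if all(abs(start / frame_rate - t) > 0.12 for t in tr):
                    damaged_runs.append((start, length))
                    break

    kwargs: dict[str, object] = dict(
        frame_rate=frame_rate,
        duration=duration,
        f0_schedule=f0_schedule,
        amplitude_start=0.2 * amp_end,
        amplitude_end=amp_end,
        amplitude_jump=1.35 if len(f0_schedule) > 1 else 1.0,
        phase_lag=0.02 * (l - r),
        damaged_runs=tuple(damaged_runs),
        seed=cell_seed,
    )
    kwargs.update(grid.base)
    kwargs.update(grid.overrides.get((sln, l, r), {}))
    return SynthConfig(**kwargs), onset_time


def generate_grid(config: GridConfig) -> dict[Condition, GAWRecord | None]:
    """Generate one recording per grid cell (``None`` marks no phonation).

    Cells where the onset rule fails emit ``None``.  Cells with SLN = 0 never
    contain a programmed event regardless of the event rule.  Each cell gets
    an independent seed derived from ``config.seed``.
    """
    conditions = config.conditions()
    children = np.random.SeedSequence(config.seed).spawn(len(conditions))
    out: dict[Condition, GAWRecord | None] = {}
    for idx, cond in enumerate(conditions):
        if not config.onset_rule(*cond):
            out[cond] = None
            continue
        cell_seed = int(children[idx].generate_state(1)[0] % 2**31)
        rng = np.random.default_rng(children[idx])
        cfg, onset_time = _cell_config(config, cond, cell_seed, rng)
        record = generate_gaw(
            cfg,
            condition=cond,
            flow_ramp=FlowRamp(),
            onset_frame=int(round(onset_time * cfg.frame_rate)),
            recording_id=f"sln{cond.sln}_l{cond.rln_left}_r{cond.rln_right}",
        )
        out[cond] = record
    return out


def generate_acoustic(
    gaw: GAWRecord,
    sample_rate: float = 50000.0,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> AcousticRecord:
    """Derive a pressure-like acoustic stand-in from a GAW recording.

    The band-limited GAW is resampled to ``sample_rate`` and differentiated
    (radiated pressure is approximately proportional to the time derivative
    of the glottal flow pulse train), normalized to unit peak, plus white
    noise.  A flat GAW yields pure noise at the configured floor.
    """
    from fractions import Fraction

    frac = Fraction(sample_rate / gaw.frame_rate).limit_denominator(1000)
    x = gaw.total - float(np.mean(gaw.total))
    y = resample_poly(x, frac.numerator, frac.denominator)
    n_out = int(round(gaw.duration * sample_rate))
    y = y[:n_out] if len(y) >= n_out else np.pad(y, (0, n_out - len(y)))
    dy = np.gradient(y) * sample_rate
    peak = float(np.max(np.abs(dy)))
    if peak > 0:
        dy = dy / peak
    rng = np.random.default_rng(seed)
    dy = dy + rng.normal(0.0, noise_sd, len(dy))
    return AcousticRecord(dy, sample_rate, recording_id=gaw.recording_id)
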