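# Methods

## Signal model and analysis pipeline

A recording is a phonation segment: total glottal area per video frame plus
left/right hemiglottal partials split at the glottal midline, at
`frame_rate` frames/s (default 3000), with a boolean mask of damaged frames
and metadata tying the segment to a stimulation condition (SLN 0–4,
left/right RLN 0–7), a linear airflow ramp (300 → 1400 mL/s over 1.5 s) and
an onset frame within the stimulation epoch.  The pipeline is:

1. **Trim**: `round(0.010 × frame_rate)` frames removed from each end
   (30 at 3000 fps); the onset frame is advanced by the leading trim so
   event times stay anchored to the flow ramp.
2. **Inclusion**: segments shorter than `round(0.25 × frame_rate)` frames
   after trimming (750 at 3000 fps) are excluded.  Damaged frames do not
   break continuity; they only invalidate the cycles that touch them.
3. **Cycle detection**: interior local maxima of the total GAW with
   prominence ≥ 5 % of the *maximum dynamic range* — the largest
   peak-minus-nearby-trough value, troughs searched within ±12.5 ms
   (±38 frames at 3000 fps, round-half-up).  The prominence floor is a
   single per-recording scalar, not per-peak, so that quiet early cycles on
   the rising ramp are judged against the same yardstick as loud late ones.
   Retained peaks are thinned greedily in decreasing height (earlier index
   wins exact ties) so that no two are closer than 3 frames; separation of
   exactly 3 is kept.  Cycles run maximum-to-maximum with the internal
   minimum at the argmin strictly between (earliest on ties); intervals are
   half-open `[start, end)`, 0-based.
4. **Cycle exclusion**: damaged overlap, then a single-pass outlier rule —
   a cycle is an outlier iff its length falls strictly outside
   [0.5×, 2.0×] of the median length in an 11-cycle window centered on it
   (shrunk at the ends), computed on the original lengths.  The inclusive
   2.0 boundary guarantees a genuine octave drop (7–8-frame cycles becoming
   15-frame cycles) is never discarded; the window and bounds are
   configurable because only the comparison-to-local-median principle is
   fixed, not its constants.
5. **Parameters** per valid cycle (LF0, DR, PHA, AP, TP, OD, CD; see
   README).  AP and TP use the min/max-ratio convention (1 = perfectly
   periodic, lower = more perturbed) and are computed only across directly
   consecutive valid cycles; pairs broken by an exclusion yield no value
   rather than zero.  PHA is normalized by the cycle length, wrapped into
   [−0.5, 0.5], with positive = left-side phase lead.
6. **Mode-change detection** on the valid-cycle LF0 sequence: a 10-point
   centered moving mean (window `[i−5, i+4]`, shrunk at the ends; a moving
   median is available via `DetectorConfig.method` — the mean is the
   default because that is the smoothing actually applied in the reference
   analysis despite its "median" label), then the first and last 5 values
   are dropped.  Position *i* is a candidate if the smoothed LF0 moves by
   ≥ 50 Hz within 10 positions and stays ≥ 50 Hz away on the same side for
   ≥ 5 consecutive positions.  Runs of nearby same-direction candidates
   merge into one event anchored at the steepest single-step change; events
   within 10 positions of either end are discarded (onset/offset
   transients).  Spans are counted on the smoothed, post-exclusion sequence
   in cycle units, so index gaps from excluded cycles do not stretch the
   span.
7. **Characterization**: medians of LF0 and DR over up to 10 valid cycles
   strictly before and strictly after the event cycle; airflow from the
   linear ramp at (onset frame / frame rate + event time), saturating at
   the ramp end.

## Synthetic generator

The generator is phenomenological: it reproduces the statistical structure
the analysis assumes, not vocal-fold physics.  Each cycle is a skewed
raised-cosine pulse from one maximum through the minimum to the next
maximum; the minimum sits at fraction CD/(CD+OD) = 1/(1+r) of the cycle for
OD:CD ratio r (r = 1 falsetto-like, r = 0.5 chest-like).  Cycle length is
`frame_rate / f0(t)` with multiplicative Gaussian jitter; amplitude follows
a linear ramp (the study design ramps flow linearly and amplitude grows
with flow; the linear amplitude–flow link is an assumption, as no published
scale ties mL/s to pixel²) with multiplicative shimmer.  Defaults
(400 Hz pre-transition, ~205 Hz post, amplitude ramp reaching a few
thousand px², 2 % jitter/shimmer, 3× perturbation boost in the 50 ms before
a transition) were chosen to match the magnitudes a high-SLN in vivo
phonation run displays.  Two deliberate modeling choices:

* **Transitions at cycle boundaries.**  F0 steps are realized between
  cycles, never mid-cycle, so programmed ground truth is unambiguous.
* **`amplitude_jump`.**  Real mode changes show a sudden dynamic-range gain
  beyond the ramp; a multiplier (grid default 1.35) applied from the first
  transition onward models it explicitly.

Left and right partials are generated with ±lag/2 phase offsets and sum to
the total *by construction* (the total is defined as their sum); per-side
noise keeps the identity exact.  Damaged runs (≤ 20 frames) zero both
partials and set the mask.  Generation is bit-reproducible from the seed.

Grid defaults: onset iff `rln_left + rln_right ≥ 2 + sln` (phonation
becomes rarer at low adduction as tension rises), events iff `sln ≥ 1`,
`min(rln) ≥ 5`, `|rln_left − rln_right| ≤ 1` (events need tension plus
strong near-symmetric adduction); SLN = 0 cells never contain programmed
events.  Both predicates are configuration, chosen to mirror the observed
trends qualitatively, and carry no quantitative claim.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: chaotic high-stimulation oscillation, gradual F0
drift under zero SLN, anterior–posterior phase "blurring" that corrupts PHA,
non-cosine pulse shapes, amplitude–frequency coupling, segmentation noise
correlated across frames.  Recovery results on synthetic grids demonstrate
the pipeline's correctness, not field performance.

## Numerical choices

* Threshold comparisons (prominence floor, 50 Hz delta) carry a 1e-9
  absolute slack: the 5 % fraction is not binary-representable and the
  boundary semantics are inclusive (a step of exactly 50 Hz is an event, a
  prominence of exactly 5 % is kept).
* Window rounding is half-up (12.5 ms × 3 frames/ms = 37.5 → 38).
* The even smoothing window introduces a half-sample lag on ramps; event
  anchoring at the steepest change is insensitive to it.
* Per-cycle DR is monotone along a noiseless ramp only when cycle
  boundaries align with the frame grid; at non-integer periods, sampled
  peak heights carry quantization ripple of a few percent.  Cycle-length
  quantization (±1 frame) likewise bounds how precisely PHA, OD:CD and TP
  recover generator settings; tests use quantization-aware tolerances.
* Flat or monotone series raise on `max_dynamic_range` (no local maximum);
  the pipeline converts this into an excluded recording with a logged
  reason rather than an error.

## Problem sizes

The test suite and the acceptance probes run entirely on synthetic data:
constant-parameter recordings of 0.5–1.5 s at 3000 fps, behavioral scans on
traces of 60–200 cycles, oracle cross-checks on 1000 random series of
20–200 samples, and one full 5 × 8 × 8 grid (320 cells, ~260 phonating,
~15 s to generate and analyze) — sizes at which every check is exact or
statistically stable while the whole suite stays fast.

## Known limitations

Peak localization is frame-accurate only (no sub-frame interpolation, as in
the reference analysis).  The detector reports all qualifying events without
classifying chaotic sections, where event counts are inherently less
reliable.  "Continuous phonation" is operationalized as the trimmed segment
length; phonation onset must be supplied as metadata, not detected.  The
acoustic channel is a derivative-based stand-in adequate for spectrogram
plumbing, not an aeroacoustic model.
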