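"""Acoustic stand-in and spectrogram of a mode change.

Derives a 50 kHz pressure-like signal from a GAW with a 400 -> 200 Hz drop
and tracks the fundamental ridge of its spectrogram (4096-sample window,
80% overlap) across the event.
"""

import numpy as np

import gawkit as gk

record = gk.generate_gaw(gk.SynthConfig(
    duration=1.0, f0_schedule=((0.0, 400.0), (0.5, 200.0)), seed=3))
acoustic = gk.generate_acoustic(record, noise_sd=0.001)
freqs, times, S = gk.spectrogram(acoustic)

band = freqs < 600.0
ridge = freqs[band][np.argmax(S[band], axis=0)]
print(f"spectrogram: {S.shape[0]} bins x {S.shape[1]} frames, "
      f"resolution {freqs[1]:.1f} Hz")
print(f"fundamental ridge before the change: {np.median(ridge[times < 0.4]):.0f} Hz")
print(f"fundamental ridge after the change:  {np.median(ridge[times > 0.6]):.0f} Hz")
# The acoustic fundamental follows the GAW LF0 and halves at the event.
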