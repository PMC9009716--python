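"""Recover the detector's constants by black-box probing.

The analysis constants (50 Hz mode-change threshold, 3-frame minimum peak
distance, 5% prominence floor) are recoverable from the pipeline's behavior
alone — useful as a self-check after changing any detection code.
"""

import numpy as np
import pandas as pd

import gawkit as gk
from gawkit.modechange import detect_mode_changes, smooth_lf0

# smallest sustained LF0 step that counts as a mode change
for step in range(1, 101):
    lf0 = pd.Series([400.0] * 100 + [400.0 - step] * 100)
    if detect_mode_changes(smooth_lf0(lf0)):
        print(f"smallest flagged LF0 step: {step} Hz")
        break

# smallest separation at which two equal peaks are both kept
for d in range(1, 10):
    x = np.zeros(300)
    x[[100, 100 + d]] = 100.0
    if len(gk.detect_peaks(x)) == 2:
        print(f"minimum retained peak separation: {d} frames")
        break

# smallest secondary prominence (% of max dynamic range) kept
for p in range(1, 16):
    x = np.zeros(1200)
    for m in (100, 200, 300):
        x[m - 10: m] = np.linspace(0, 1000, 11)[:-1]
        x[m: m + 11] = np.linspace(1000, 0, 11)
    x[[600, 700, 800, 900]] = 10.0 * p
    if {600, 700, 800, 900} <= set(gk.detect_peaks(x)):
        print(f"minimum retained prominence: {p}% of max dynamic range")
        break
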