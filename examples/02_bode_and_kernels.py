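"""Frequency-domain view of the ON/OFF kernels.

Prints the first kernel taps at the reference operating point and the Bode
magnitude at a few modulation frequencies.  Both filters are high-pass for
large w; their DC gain is 1-w, so w=1 removes all sustained (DC) signal and
w=0 leaves the input untouched.
"""

import numpy as np

from adaptrans import bode_curves, build_kernels, transfer_function

w, a = 0.5, 0.6
pair = build_kernels(w, a, a, K=10)
print("h_on :", np.round(pair.h_on, 4))
print("h_off:", np.round(pair.h_off, 4))
print(f"kernel sums: {pair.h_on.sum():.4f}, {pair.h_off.sum():.4f} (= 1-w)")

dt = 0.005  # 5 ms bins -> Nyquist 100 Hz
freqs = np.array([0.0, 5.0, 20.0, 60.0, 95.0])
for polarity in ("on", "off"):
    mag, _ = bode_curves(w, a, polarity, freqs, dt)
    line = "  ".join(f"{f:5.0f} Hz: {m:+6.2f} dB" for f, m in zip(freqs, mag))
    print(f"{polarity.upper():3s} magnitude  {line}")
print(f"DC gain check: H(1) = {transfer_function(w, a, 'on', 1.0).real:.4f}"
      f" (1-w = {1-w})")
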