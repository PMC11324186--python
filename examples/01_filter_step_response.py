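"""Step response of the paired ON/OFF filter.

Builds a one-band binary step and filters it.  The printed amplitudes are the
filter's defining signature: onset of 1 on the ON channel, -w on the OFF
channel, a shared sustained level of 1-w while the sound stays on, and the
mirrored pair (-w, 1) at sound offset.
"""

import numpy as np

from adaptrans import AdapTransParams, apply_adaptrans, make_step

w, a = 0.5, 0.6
params = AdapTransParams(w=[w], a_on=[a], a_off=[a], dt=0.005,
                         band_freqs=[1000.0])
stim = make_step(F=1, T=400, onset=120, offset=300, dt=0.005,
                 band_freqs=[1000.0])
out = apply_adaptrans(stim, params, K=100)
on, off = out.on[0], out.off[0]

print(f"filter parameters: w={w}, a={a} (tau = {-1/np.log(a):.2f} steps)")
print(f"ON  at onset   : {on[120]:+.6f}   (the step amplitude)")
print(f"OFF at onset   : {off[120]:+.6f}   (-w)")
print(f"sustained ON   : {on[299]:+.6f}   (1 - w, shared by both channels)")
print(f"sustained OFF  : {off[299]:+.6f}")
print(f"ON  at offset  : {on[300]:+.6f}   (-w)")
print(f"OFF at offset  : {off[300]:+.6f}   (full offset response)")
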