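"""Frequency-wise ON/OFF decomposition of a three-band stimulus.

Three bands switch off at 0.3, 0.4 and 0.5 s; each band's OFF channel peaks
only at its own offset, so a weighted sum over the six band-polarity channels
(a 15-parameter model) can reproduce population traces with distinct offset
events.  Prints the gradient fit of that model to a self-generated target and
the closed-form least-squares identification of its readout.
"""

import numpy as np

from adaptrans.experiments import exp_multiband

res = exp_multiband(seed=0, max_epochs=800)
print(f"final MSE of the gradient fit : {res.final_mse:.2e}")
print(f"trace correlation with target : "
      f"{np.corrcoef(res.trace_true, res.trace_fitted)[0, 1]:.5f}")
print(f"readout recovered by least squares (max rel. error): "
      f"{res.lstsq_max_relative_error:.2e}")
print(f"readout reached by gradient descent (max rel. error): "
      f"{res.gradient_max_relative_error:.2f}")
print("\nthe trace is matched almost perfectly; the gradient-descent readout "
      "differs from the\ngenerating one because rectified sustained channels "
      "are nearly collinear with the bias,\nwhile the direct solve shows the "
      "model itself is identifiable.")
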