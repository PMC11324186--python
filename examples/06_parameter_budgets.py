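"""Learnable-parameter budgets of every backbone/prefilter/dataset geometry.

The paired prefilter adds 3 parameters per band and doubles the input layer;
for the hidden-layer models the hidden width is halved in compensation, so
budgets stay level with the single-channel controls.  Cells flagged
"excluded" carry a documented architectural ambiguity and are reported
without being asserted.
"""

from adaptrans.experiments import exp_param_table

table = exp_param_table()
print(table.to_string(index=False))
clean = table[~table.excluded]
print(f"\n{len(clean)} unambiguous cells, "
      f"{(clean.computed == clean.published).sum()} match published budgets "
      f"exactly.")
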