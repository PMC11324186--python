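# Methods

## The filter model

Each cochleagram band x_f[n] (log-compressed power in band f at time bin n,
bin width dt seconds) is convolved with a pair of causal, first-order,
biphasic kernels:

    h_on[0] = 1        h_on[d]  = −w · C_on  · a_on^{d−1}    d = 1 … K−1
    h_off[0] = −w      h_off[d] =      C_off · a_off^{d−1}   d = 1 … K−1

Interpretation: the output is a weighted difference between the present
sample and an exponential moving average (EMA) of the past.  `a = exp(−1/τ)`
sets the EMA memory (τ in bins); `w` sets the transient/sustained trade-off
— w = 0 leaves the input unchanged (the ON kernel collapses to a Kronecker
delta), w = 1 computes a pure temporal derivative and makes the two kernels
exact opposites.  `C` normalizes the exponential tail to unit sum, giving
both kernels DC gain 1 − w.

Consequences used throughout the tests: a unit step elicits an ON onset of
exactly 1 and an OFF onset of −w; both channels share the sustained level
1 − w; at termination the ON channel deflects by −w and the OFF channel
responds with A_OFF(T) = 1 − a^T for a sound of duration T bins — increasing
and saturating in T, independent of w.  In the z-domain,

    H_ON(z)  = (1 − (a + w − aw) z^{−1}) / (1 − a z^{−1})
    H_OFF(z) = (−w + (1 − a + aw) z^{−1}) / (1 − a z^{−1})

both high-pass for large w, with the OFF filter turning low-pass for small w.

Symmetry caveat: with a_on = a_off the *event amplitudes* are symmetric
across polarities (ON onset ↔ OFF offset, ON offset ↔ OFF onset), but the
full ON response to an up-step equals the OFF response to a down-step
sample-for-sample only at w = 1 (for w < 1 the two relaxations differ:
1 − wC·S_k versus 1 − C·S_k).  The tests assert exactly these two facts.

### Parameters, units, defaults

| parameter | meaning | default / initialization |
|---|---|---|
| w (per band) | transient vs sustained trade-off, ∈ [0,1] | 0.75 — cortical onset-sustained-offset neurons keep a small but nonzero sustained response |
| a_on, a_off (per band) | EMA decay, ∈ (0,1); τ = −1/ln a | τ(f) = 500 − 105·log10(f) ms, floored at 1 bin |
| dt | seconds per time bin | dataset property (5 or 10 ms typical) |
| K | kernel truncation length, bins | 3·τ_max + 1 at initialization |

The log in the τ(f) rule is base-10: a natural log would make τ negative
over most of the audible range, while base-10 gives 40–260 ms across
0.2–22.6 kHz, the order observed physiologically.  The floor at 1 bin guards
against the rule going negative above ~57 kHz.

### Numerical choices

- **Truncation.** K = 3·τ_max + 1 retains at least 1 − e^{−3} ≈ 95% of the
  infinite exponential mass for every band.  K is fixed when a model is
  built and *not* recomputed as τ is learned (stable memory layout; learned
  constants stay near their initialization in practice).  Kernel *values*
  are rebuilt from the current parameters at every forward pass.
- **Renormalization.** After truncation, C is the reciprocal of the finite
  geometric sum (not 1 − a), so kernel sums and the step-response table are
  exact at any K.  The residual difference from the untruncated filter is
  O(a^{K−1}); analyses that compare against closed forms at 1e−6 use
  K large enough that a^{K−1} < 1e−9.
- **Padding.** Inputs are left-padded with K−1 copies of their first column
  ("replicate"), so outputs have the input's length and are defined from
  t = 0.  A consequence worth knowing: a stimulus that is already on at its
  first bin is treated as on for all past time.  Step/ramp experiments
  therefore begin with at least one silent bin when a true onset is intended.
- **Constraints under learning.** w and a are stored as unconstrained reals
  and squashed through a logistic map, so any gradient update keeps
  w ∈ (0,1) and a ∈ (0,1).
- **Rectification** (half-wave, ReLU) is a separate operation between the
  filter and the backbone, not fused into the filter.

## Backbones and parameter budgets

All backbones share one contract: causal (left-replicate padding), no
temporal downsampling, one output per input bin and per unit.

- **L** — full-band causal STRF convolution + bias.
- **LN** — L, then batch normalization, then a sigmoid.  The normalization
  here carries no learnable affine pair: the published budgets print
  identical counts for L and LN, which forces the affine-free reading.
  (A side effect: the pre-sigmoid bias is normalized away and has a zero
  gradient; it is still a parameter, as budget accounting requires.)
- **NRF** — H parallel STRFs → BN (affine) → sigmoid → purely linear readout
  (weights + bias, no output squashing; forced by exact agreement with all
  six published NRF budget cells).
- **DNet** — short STRFs (5-bin span) → BN → causal normalized exponential
  smoothing with a learnable per-hidden-unit time constant τ = 1 + d²
  (always ≥ 1 bin; DC gain exactly 1) → sigmoid → linear readout → output
  smoothing with one more learnable constant per output unit.  The smoothing
  kernel is truncated at `smooth_len` bins (default 50).
- **CNN2D** — three conv layers (10 channels; BN + LeakyReLU 0.1), causal in
  time, valid (no-pad) in frequency, then a two-layer head (90 hidden units)
  applied at every bin.  The per-layer kernel span (F, T) is read as applying
  to all three layers; under this reading the computed budgets differ from
  the published ones by 3 on two of the three dataset geometries and by more
  on the third, so CNN budgets are reported but never asserted.  One DNet
  cell differs by exactly 2 from the architecture that matches every other
  cell and is treated as a typo, likewise excluded.

Prefilter modes: `none` (raw, 1 channel), `ic_adaptation` (fixed
single-channel baseline: ON filter with w = 1, frozen τ, rectified — offset
information is discarded by construction), `adaptrans` (2 learnable
rectified channels), `adaptrans_plus_raw` (those plus the raw spectrogram).
With the paired prefilter the hidden width of NRF/DNet is halved so total
budgets stay level with the controls.

## Fitting protocol

Adaptive-moment optimizer (β₁ = 0.9, β₂ = 0.999, decoupled weight decay 0),
constant learning rate 1e−3, MSE loss on the per-bin PSTH, batch size 1
(small sets) or 16 (large sets, by gradient accumulation), validation after
every epoch, best checkpoint kept, stop after 50 epochs without improvement.
An epoch cap (default 1000) bounds runtime on top of patience.  Validation
loss is the per-bin mean MSE over the concatenated validation bins (the
per-clip vs per-bin choice is open; per-bin is recorded in the run log).
Splits are clip-level: floor(10%) validation, floor(20%) test, remainder
train (keeping train largest; validation and test are never left empty, so
tiny sets still get one clip each), or a pinned test list with an 80/20
train/val split of the rest.  Filter parameters are updated by the same
gradient steps as the backbone.

All gradients come from a small reverse-mode array autodiff engine inside
the package (`adaptrans._autodiff`) — double precision, CPU, covering
exactly the operations the models need; its gradients are tested against
central finite differences for every operation.  Given a seed, fitting is
deterministic.

## Evaluation statistics

With N trials r_n over T bins, r = mean_n r_n is the PSTH.  CC_raw is the
Pearson correlation between r and the prediction r̂.  Signal power

    SP = [Var(Σ_n r_n) − Σ_n Var(r_n)] / (N(N−1))

estimates the repeatable response variance (unbiased under independent
additive trial noise; all variances use the N−1 normalization consistently,
so CC_norm·CC_max = CC_raw holds exactly).  CC_norm = Cov(r, r̂)/√(SP·Var r̂)
and CC_max = √(SP/Var r) (clipped to [0,1]).  Policies: with one trial,
CC_norm falls back to CC_raw (conservative); a non-positive SP estimate
(possible on noisy, small-N data) yields NaN with a warning rather than a
silently clipped value.  Metrics are computed after concatenating all clips
of an evaluation set along time.

Coherence uses Welch's method with 500 ms segments, Hann window, 50%
overlap (the segment length is the stated choice; window and overlap are
this package's fixed defaults), values clipped to [0,1].  Its ceiling is the
average coherence between split-half PSTHs over up to 126 deterministic
lexicographic half/half partitions (complements not double-counted), or a
flat 1 for single-trial data.

## Synthetic data: what it does and does not emulate

The teacher simulator produces PSTH = bias + Σ weights·rectify(filter(stim))
and adds i.i.d. Gaussian noise per trial.  It emulates the clip/trial
structure of real recording sets (tens of clips, 5–20 repeats, 5–10 ms
bins) and gives exact ground truth for recovery studies.  It does not
emulate spiking statistics (Poisson-like variance scaling), slow drift,
neuron-to-neuron heterogeneity beyond the readout, or any nonlinearity
beyond rectification — so passing recovery tests demonstrate correctness of
the machinery, not expected performance on biological recordings.  Teacher
stimuli are random per-band binary telegraph processes (switch probability
0.02/bin): every band gets its own onsets and offsets, which is what makes
per-band parameters identifiable.  The standard recovery condition uses 20
clips of 500 bins, 16 bands, 10 repeats, noise σ = 0.05.

A known degeneracy, exposed by the three-band readout experiment: the
rectified ON and OFF channels share their sustained component, which is in
turn collinear with the bias regressor.  Gradient descent therefore drives
the predicted *trace* onto the target quickly (MSE < 1e−4) while the
(readout, w) combination can wander along a near-flat valley; a direct
least-squares solve on the channels — reported alongside — identifies the
readout to machine precision.  Recovery claims in this package are
therefore stated either for the well-conditioned telegraph-stimulus setting
(where w is recovered to a few hundredths) or via the least-squares oracle.

## Problem sizes

Test and example runs use scaled-down geometries chosen as sensible
demonstration sizes: recovery at F = 16, T = 500, 20 clips; examples at
F = 8.  Published-geometry models (up to F = 49, T = 41) are instantiated
and budget-checked but not trained in the suite.

## Known limitations

- No second-order or growing-exponential onset kernels (the initial delta
  means instantaneous response buildup).
- No per-neuron asymmetric ON/OFF STRF parameterization.
- The CNN budget ambiguity above; CNN forward semantics follow the stated
  reading.
- `log_stft_cochleagram` is a minimal front end (log-pooled magnitude STFT),
  not a gammatone/mel reproduction of any dataset's pipeline; real datasets
  ship precomputed cochleagrams and are read through the HDF5 container.
- Population fitting shares the trunk and averages MSE across heads; for
  L/LN (no trunk) it reduces to independent per-unit STRFs fitted jointly.
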