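"""Paired ON/OFF biphasic exponential filters ("AdapTrans") and analysis tools.

The model decomposes each frequency band of a cochleagram into an ON and an
OFF channel with a pair of causal, first-order, biphasic filters.  Each kernel
is a weighted difference between the current sample and an exponential moving
average (EMA) of the recent past:

    h_on[0]  = 1,   h_on[d]  = -w * C_on  * a_on**(d-1)   (d >= 1)
    h_off[0] = -w,  h_off[d] =      C_off * a_off**(d-1)  (d >= 1)

where ``a = exp(-1/tau)`` sets the EMA time constant (in time steps), ``w`` in
[0, 1] sets the transient/sustained trade-off, and ``C`` normalizes the
exponential tail to unit sum.  Both kernels have DC gain ``1 - w``: a unit
step yields an ON onset of 1, an OFF onset of -w, a shared sustained level of
``1 - w``, an ON offset of -w and an OFF offset of (up to) 1.

Time constants are initialized from band center frequency with the
logarithmic rule ``tau(f) = 500 - 105*log10(f)`` milliseconds, reflecting
the slower adaptation of low-frequency auditory channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AdapTransParams",
    "KernelPair",
    "PolarSpectrogram",
    "init_time_constants",
    "a_from_tau",
    "tau_from_a",
    "kernel_length",
    "build_kernels",
    "apply_adaptrans",
    "rectify",
    "transfer_function",
    "bode_curves",
    "offset_amplitude_closed_form",
    "ic_adaptation",
    "kernels_to_csv",
]

# coefficients of the tau(f) initialization rule, in milliseconds
TAU_INTERCEPT_MS = 500.0
TAU_SLOPE_MS_PER_DECADE = 105.0
W_INIT = 0.75


def init_time_constants(band_freqs, dt):
    """Initial per-band EMA time constants, in time steps.

    tau(f) = (500 - 105*log10(f)) ms, converted to steps of ``dt`` seconds
    and floored at one step (the rule goes negative above ~57 kHz).

    Parameters
    ----------
    band_freqs : array-like of float
        Band center frequencies in Hz, all > 0.
    dt : float
        Seconds per time step, > 0.

    Returns
    -------
    numpy.ndarray
        Time constants in time steps (float), one per band, >= 1.
    """
    band_freqs = np.asarray(band_freqs, dtype=float)
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if band_freqs.size == 0 or np.any(band_freqs <= 0):
        raise ValueError("band frequencies must be positive")
    tau_ms = TAU_INTERCEPT_MS - TAU_SLOPE_MS_PER_DECADE * np.log10(band_freqs)
    tau_steps = tau_ms * 1e-3 / dt
    return np.maximum(tau_steps, 1.0)


def a_from_tau(tau):
    """Map a time constant (steps, >= 1) to the EMA decay factor a = exp(-1/tau)."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 1):
        raise ValueError("time constants must be >= 1 step")
    return np.exp(-1.0 / tau)


def tau_from_a(a):
    """Inverse of :func:`a_from_tau`: tau = -1/ln(a) for a in (0, 1)."""
    a = np.asarray(a, dtype=float)
    if np.any((a <= 0) | (a >= 1)):
        raise ValueError("decay factors must lie strictly in (0, 1)")
    return -1.0 / np.log(a)


@dataclass
class AdapTransParams:
    """Per-band filter parameters (w, a_on, a_off).

    ``w`` in [0, 1] is the transient/sustained trade-off; ``a_on``/``a_off``
    in (0, 1) are the EMA decay factors of the ON and OFF kernels.  ``dt`` is
    seconds per time step and ``band_freqs`` the band center frequencies (Hz).
    """

    w: np.ndarray
    a_on: np.ndarray
    a_off: np.ndarray
    dt: float
    band_freqs: np.ndarray
    trainable: bool = True

    def __post_init__(self):
        self.w = np.atleast_1d(np.asarray(self.w, dtype=float))
        self.a_on = np.atleast_1d(np.asarray(self.a_on, dtype=float))
        self.a_off = np.atleast_1d(np.asarray(self.a_off, dtype=float))
        self.band_freqs = np.atleast_1d(np.asarray(self.band_freqs, dtype=float))
        n = self.n_bands
        if not (len(self.w) == len(self.a_on) == len(self.a_off) == n):
            raise ValueError("w, a_on, a_off, band_freqs must have equal length")
        self.validate()

    @property
    def n_bands(self):
        return len(self.band_freqs)

    def validate(self):
        if np.any((self.w < 0) | (self.w > 1)):
            raise ValueError("w must lie in [0, 1]")
        for name, a in (("a_on", self.a_on), ("a_off", self.a_off)):
            if np.any((a <= 0) | (a >= 1)):
                raise ValueError(f"{name} must lie strictly in (0, 1)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def tau_on(self):
        """ON time constants in steps."""
        return tau_from_a(self.a_on)

    @property
    def tau_off(self):
        """OFF time constants in steps."""
        return tau_from_a(self.a_off)

    @classmethod
    def from_frequencies(cls, band_freqs, dt, w=W_INIT, trainable=True):
        """Standard initialization: tau from the logarithmic rule, w = 0.75."""
        band_freqs = np.atleast_1d(np.asarray(band_freqs, dtype=float))
        tau = init_time_constants(band_freqs, dt)
        a = a_from_tau(tau)
        w_arr = np.full(len(band_freqs), float(w))
        return cls(w=w_arr, a_on=a.copy(), a_off=a.copy(), dt=dt,
                   band_freqs=band_freqs, trainable=trainable)


@dataclass
class KernelPair:
    """Truncated ON/OFF kernel pair for one band (index 0 = present sample)."""

    h_on: np.ndarray
    h_off: np.ndarray
    c_on: float
    c_off: float

    @property
    def length(self):
        return len(self.h_on)


def kernel_length(params: AdapTransParams) -> int:
    """Truncation length K = 3*tau_max + 1 (steps), tau_max over bands/polarities.

    At this length at least 1 - exp(-3) (about 95%) of the infinite
    exponential tail mass is retained for every band.  K is fixed at model
    construction and not recomputed as parameters are learned.
    """
    tau_max = max(params.tau_on.max(), params.tau_off.max())
    return int(np.ceil(3.0 * tau_max)) + 1


def _exp_tail(a: float, n: int) -> np.ndarray:
    """Normalized truncated exponential [C, C*a, ..., C*a^(n-1)] summing to 1."""
    powers = a ** np.arange(n)
    return powers / powers.sum()


def build_kernels(w: float, a_on: float, a_off: float, K: int) -> KernelPair:
    """Build the truncated ON/OFF kernel pair of length ``K`` for one band.

    The exponential part is renormalized over its K-1 retained terms so that
    it sums exactly to 1 (and hence the full kernels each sum to 1 - w)
    despite truncation.
    """
    if K < 2:
        raise ValueError(f"kernel length must be >= 2, got K={K}")
    tail_on = _exp_tail(a_on, K - 1)
    tail_off = _exp_tail(a_off, K - 1)
    h_on = np.concatenate(([1.0], -w * tail_on))
    h_off = np.concatenate(([-w], tail_off))
    return KernelPair(h_on=h_on, h_off=h_off,
                      c_on=float(tail_on[0]), c_off=float(tail_off[0]))


@dataclass
class PolarSpectrogram:
    """2 x F x T ON/OFF filtered stimulus (channel 0 = ON, channel 1 = OFF)."""

    values: np.ndarray
    band_freqs: np.ndarray
    dt: float
    rectified: bool = False
    source: object = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != 2:
            raise ValueError("polar spectrogram must have shape (2, F, T)")

    @property
    def on(self):
        return self.values[0]

    @property
    def off(self):
        return self.values[1]


def _causal_filter_bank(values: np.ndarray, kernels: list[np.ndarray]) -> np.ndarray:
    """Causally convolve each row of ``values`` with its own kernel.

    Rows are left-padded with K-1 copies of their first sample ('replicate'
    padding) so the output has the same length as the input and is defined
    from t = 0.
    """
    F, T = values.shape
    out = np.empty((F, T))
    for f in range(F):
        h = kernels[f]
        K = len(h)
        padded = np.concatenate((np.full(K - 1, values[f, 0]), values[f]))
        out[f] = np.convolve(padded, h, mode="valid")
    return out


def apply_adaptrans(cochleagram, params: AdapTransParams, K: int | None = None) -> PolarSpectrogram:
    """Filter a cochleagram into its 2-channel ON/OFF polar spectrogram.

    No rectification is applied; see :func:`rectify`.  Output has the same
    F x T geometry as the input (replicate padding, no downsampling).
    """
    values = np.asarray(cochleagram.values, dtype=float)
    if values.shape[0] != params.n_bands:
        raise ValueError(
            f"cochleagram has {values.shape[0]} bands, params expect {params.n_bands}")
    if K is None:
        K = kernel_length(params)
    pairs = [build_kernels(params.w[f], params.a_on[f], params.a_off[f], K)
             for f in range(params.n_bands)]
    on = _causal_filter_bank(values, [p.h_on for p in pairs])
    off = _causal_filter_bank(values, [p.h_off for p in pairs])
    return PolarSpectrogram(values=np.stack([on, off]),
                            band_freqs=params.band_freqs, dt=params.dt,
                            rectified=False, source=cochleagram)


def rectify(x: PolarSpectrogram) -> PolarSpectrogram:
    """Half-wave rectification (ReLU), applied between the filter and a backbone."""
    return PolarSpectrogram(values=np.maximum(x.values, 0.0),
                            band_freqs=x.band_freqs, dt=x.dt,
                            rectified=True, source=x.source)


def transfer_function(w, a, polarity, z):
    """Z-domain transfer function of one kernel (untruncated IIR form).

        H_ON(z)  = (1 - (a + w - a w) z^-1) / (1 - a z^-1)
        H_OFF(z) = (-w + (1 - a + a w) z^-1) / (1 - a z^-1)

    Both have DC gain H(1) = 1 - w.  ``z`` may be an array of complex points.
    """
    z = np.asarray(z, dtype=complex)
    if np.any(np.isclose(z, a)):
        raise ZeroDivisionError("evaluation at the filter pole z = a")
    zinv = 1.0 / z
    denom = 1.0 - a * zinv
    pol = str(polarity).lower()
    if pol == "on":
        return (1.0 - (a + w - a * w) * zinv) / denom
    if pol == "off":
        return (-w + (1.0 - a + a * w) * zinv) / denom
    raise ValueError(f"polarity must be 'on' or 'off', got {polarity!r}")


def bode_curves(w, a, polarity, freqs_hz, dt):
    """Magnitude (dB) and phase (rad) of one kernel on a grid of frequencies.

    Frequencies must lie strictly below the Nyquist frequency 1/(2 dt).
    """
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    nyquist = 1.0 / (2.0 * dt)
    if np.any((freqs_hz < 0) | (freqs_hz >= nyquist)):
        raise ValueError(f"frequencies must lie in [0, {nyquist}) Hz")
    z = np.exp(1j * 2.0 * np.pi * freqs_hz * dt)
    h = transfer_function(w, a, polarity, z)
    with np.errstate(divide="ignore"):
        mag_db = 20.0 * np.log10(np.abs(h))
    return mag_db, np.angle(h)


def offset_amplitude_closed_form(T, a):
    """Closed-form OFF peak at termination of a length-T unit step: 1 - a**T.

    Independent of w, strictly increasing in T, saturating at 1.
    """
    T = np.asarray(T)
    if np.any(T < 1):
        raise ValueError("step duration must be >= 1 time step")
    return 1.0 - np.asarray(a, dtype=float) ** T


def ic_adaptation(cochleagram, params: AdapTransParams | None = None,
                  K: int | None = None) -> np.ndarray:
    """Single-channel adaptation baseline: ON filter with w = 1, fixed taus, ReLU.

    The fully transient special case of the paired filter: sustained level is
    1 - w = 0 and offsets (negative ON deflections) are discarded by the
    rectification, so only onset information survives.  Time constants are
    fixed at their frequency-rule initialization (non-learnable).

    Returns an F x T array.
    """
    if params is None:
        params = AdapTransParams.from_frequencies(
            cochleagram.band_freqs, cochleagram.dt, trainable=False)
    fixed = AdapTransParams(w=np.ones(params.n_bands), a_on=params.a_on,
                            a_off=params.a_off, dt=params.dt,
                            band_freqs=params.band_freqs, trainable=False)
    polar = apply_adaptrans(cochleagram, fixed, K=K)
    return np.maximum(polar.on, 0.0)


def kernels_to_csv(params: AdapTransParams, path, K: int | None = None):
    """Dump per-band kernel values as CSV (band_hz, lag_steps, h_on, h_off)."""
    import pandas as pd

    if K is None:
        K = kernel_length(params)
    rows = []
    for f in range(params.n_bands):
        pair = build_kernels(params.w[f], params.a_on[f], params.a_off[f], K)
        for lag in range(K):
            rows.append((params.band_freqs[f], lag, pair.h_on[lag], pair.h_off[lag]))
    pd.DataFrame(rows, columns=["band_hz", "lag_steps", "h_on", "h_off"]).to_csv(
        path, index=False)
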