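"""Encoding-model backbones (L, LN, NRF, DNet, 2D-CNN) with optional ON/OFF
prefiltering, exact parameter budgeting, and population readout.

All backbones share the same contract: input is a cochleagram, output is a
predicted response with one value per input time bin (no temporal
downsampling) and per output unit.  Every temporal operation is causal —
the prediction at bin t depends only on stimulus bins <= t — via left
replicate padding.

The prefilter modes are:

``none``
    raw cochleagram, 1 channel;
``ic_adaptation``
    fixed single-channel adaptation baseline (ON filter, w = 1, frozen
    time constants, rectified);
``adaptrans``
    learnable paired ON/OFF filtering, rectified, 2 channels — the filter's
    (w, a_on, a_off) are optimized jointly with the backbone;
``adaptrans_plus_raw``
    the 2 rectified channels plus the raw cochleagram, 3 channels.

When comparing against the published parameter budgets, the hidden width H of
NRF and DNet is halved under ``adaptrans`` so total budgets stay level with
the single-channel controls.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, asdict

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor, concatenate, einsum, leaky_relu, relu, sigmoid
from .filters import AdapTransParams, kernel_length, ic_adaptation

__all__ = [
    "ModelConfig",
    "BACKBONES",
    "PREFILTERS",
    "prefilter_channels",
    "count_parameters",
    "build_model",
    "AdapTransLayer",
    "LinearModel",
    "LNModel",
    "NRFModel",
    "DNetModel",
    "CNN2DModel",
    "save_checkpoint",
    "load_checkpoint",
    "strf_to_csv",
]

BACKBONES = ("L", "LN", "NRF", "DNet", "CNN2D")
PREFILTERS = ("none", "ic_adaptation", "adaptrans", "adaptrans_plus_raw")


def prefilter_channels(prefilter: str) -> int:
    """Number of input channels presented to the backbone."""
    try:
        return {"none": 1, "ic_adaptation": 1, "adaptrans": 2,
                "adaptrans_plus_raw": 3}[prefilter]
    except KeyError:
        raise ValueError(f"unknown prefilter mode {prefilter!r}") from None


@dataclass
class ModelConfig:
    """Backbone + prefilter specification.

    ``F`` is the number of frequency bins, ``T`` the temporal span (delays) of
    the first-layer spectro-temporal kernels, ``H`` the hidden width,
    ``n_outputs`` the number of jointly fitted units (1 = single-unit model).
    ``smooth_len`` is the truncation length of DNet's exponential smoothing
    kernels.
    """

    backbone: str = "L"
    prefilter: str = "none"
    F: int = 16
    T: int = 10
    H: int = 20
    n_outputs: int = 1
    use_batchnorm: bool = True
    l_batchnorm: bool = False
    dt: float = 0.005
    band_freqs: np.ndarray | None = None
    smooth_len: int = 50
    cnn_channels: int = 10
    cnn_fc: int = 90

    def __post_init__(self):
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        prefilter_channels(self.prefilter)  # validates
        if self.n_outputs < 1:
            raise ValueError("n_outputs must be >= 1")
        if self.band_freqs is None:
            self.band_freqs = np.geomspace(500.0, 22627.0, self.n_bands)
        self.band_freqs = np.asarray(self.band_freqs, dtype=float)
        if len(self.band_freqs) != self.n_bands:
            raise ValueError(f"band_freqs must have length {self.n_bands}")

    @property
    def n_bands(self):
        """Number of frequency bands of the input cochleagram."""
        return self.F

    @property
    def channels(self):
        return prefilter_channels(self.prefilter)


def count_parameters(config: ModelConfig) -> int:
    """Exact learnable-parameter count of a configured model.

    Counting rules (verified against the published per-dataset budgets):
    the paired prefilter contributes 3 parameters per band when learnable;
    batch normalization contributes a (scale, shift) pair per normalized unit
    in NRF/DNet/CNN but is affine-free in L/LN; DNet learns one smoothing
    time constant per hidden unit plus one per output unit.
    """
    F, T, H, N, C = config.F, config.T, config.H, config.n_outputs, config.channels
    adap = 3 * F if config.prefilter in ("adaptrans", "adaptrans_plus_raw") else 0
    b = config.backbone
    if b in ("L", "LN"):
        return N * (C * F * T + 1) + adap
    if b == "NRF":
        return H * C * F * T + H + 2 * H + N * (H + 1) + adap
    if b == "DNet":
        return H * C * F * T + H + 2 * H + H + N * (H + 1) + N + adap
    if b == "CNN2D":
        if not isinstance(config, CNNConfig):
            raise TypeError("CNN2D budgets require a CNNConfig (kernel spans "
                            "and input band count differ)")
        ch, fc = config.cnn_channels, config.cnn_fc
        adap = 3 * config.n_bands_in if adap else 0
        # conv kernels span (F, T) as given in the config at every layer
        f_out = config.n_freq_out
        conv = (C * ch * F * T + ch) + 2 * (ch * ch * F * T + ch)
        bn = 3 * 2 * ch
        head = (ch * f_out * fc + fc) + N * (fc + 1)
        return conv + bn + head + adap
    raise ValueError(config.backbone)


# CNN frequency geometry helper: with valid (no-pad) frequency convolutions the
# band axis shrinks by (F_kernel - 1) per layer.
def _cnn_freq_out(n_bands: int, f_kernel: int) -> int:
    out = n_bands - 3 * (f_kernel - 1)
    if out < 1:
        raise ValueError(
            f"frequency axis shrinks to {out} after 3 valid convolutions "
            f"({n_bands} bands, kernel {f_kernel})")
    return out


def _logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


class AdapTransLayer:
    """Differentiable paired ON/OFF filtering with learnable (w, a_on, a_off).

    Parameters are stored as unconstrained reals and squashed through a
    logistic map so w and a stay in (0, 1) under any gradient update.  The
    truncation length K is fixed from the initial time constants (3 tau_max + 1)
    and not recomputed as the constants are learned; kernel values are rebuilt
    from the current parameters at every forward pass.
    """

    def __init__(self, band_freqs, dt, w_init=0.75, trainable=True):
        init = AdapTransParams.from_frequencies(band_freqs, dt, w=w_init)
        self.band_freqs = init.band_freqs
        self.dt = dt
        self.K = kernel_length(init)
        self.trainable = trainable
        self.u_w = Tensor(_logit(init.w), requires_grad=trainable)
        self.u_a_on = Tensor(_logit(init.a_on), requires_grad=trainable)
        self.u_a_off = Tensor(_logit(init.a_off), requires_grad=trainable)

    def parameters(self):
        return [self.u_w, self.u_a_on, self.u_a_off] if self.trainable else []

    @property
    def current_params(self) -> AdapTransParams:
        """Constrained view of the current parameter values."""
        s = lambda u: 1.0 / (1.0 + np.exp(-u.data))
        return AdapTransParams(w=s(self.u_w), a_on=np.clip(s(self.u_a_on), 1e-9, 1 - 1e-9),
                               a_off=np.clip(s(self.u_a_off), 1e-9, 1 - 1e-9),
                               dt=self.dt, band_freqs=self.band_freqs,
                               trainable=self.trainable)

    def _reversed_tail(self, a: Tensor) -> Tensor:
        """Normalized exponential tail in reversed-time order, shape (F, K-1)."""
        F = len(self.band_freqs)
        exponents = np.arange(self.K - 2, -1, -1, dtype=float)  # oldest first
        log_a = a.log().reshape(F, 1)
        powers = (log_a * exponents).exp()
        return powers / powers.sum(axis=1, keepdims=True)

    def forward(self, x: Tensor) -> Tensor:
        """Filter an (F, T) input into its (2, F, T) ON/OFF representation."""
        F, T = x.shape
        w = sigmoid(self.u_w).reshape(F, 1)
        a_on = sigmoid(self.u_a_on)
        a_off = sigmoid(self.u_a_off)
        ones = Tensor(np.ones((F, 1)))
        # kernels in reversed-time order (oldest lag first, present sample last)
        h_on_rev = concatenate([self._reversed_tail(a_on) * (-w), ones], axis=1)
        h_off_rev = concatenate([self._reversed_tail(a_off), -w], axis=1)
        windows = x.pad_left_replicate(self.K - 1).unfold(self.K)  # (F, T, K)
        on = einsum("ftk,fk->ft", windows, h_on_rev)
        off = einsum("ftk,fk->ft", windows, h_off_rev)
        return concatenate([on.reshape(1, F, T), off.reshape(1, F, T)], axis=0)


class BatchNorm:
    """Per-channel normalization over all non-channel axes, with running
    statistics for evaluation mode and an optional learnable affine pair."""

    def __init__(self, n_channels, affine=True, momentum=0.1, eps=1e-5):
        self.affine = affine
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        if affine:
            self.gamma = Tensor(np.ones(n_channels), requires_grad=True)
            self.beta = Tensor(np.zeros(n_channels), requires_grad=True)

    def parameters(self):
        return [self.gamma, self.beta] if self.affine else []

    def forward(self, x: Tensor, training: bool) -> Tensor:
        axes = tuple(range(1, x.ndim))
        shape = (x.shape[0],) + (1,) * (x.ndim - 1)
        if training:
            mean = x.mean(axis=axes, keepdims=True)
            var = ((x - mean) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
            xhat = (x - mean) / ((var + self.eps) ** 0.5)
        else:
            mean = self.running_mean.reshape(shape)
            std = np.sqrt(self.running_var.reshape(shape) + self.eps)
            xhat = (x - mean) / std
        if self.affine:
            xhat = xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)
        return xhat


def _causal_conv_full_band(x: Tensor, weights_rev: Tensor, n_lags: int) -> Tensor:
    """Full-band causal temporal convolution.

    ``x`` is (C, F, T); ``weights_rev`` is (U, C, F, L) in reversed-time order
    (index l = L-1 is the present sample).  Returns (U, T).
    """
    windows = x.pad_left_replicate(n_lags - 1).unfold(n_lags)  # (C, F, T, L)
    return einsum("cftl,ucfl->ut", windows, weights_rev)


def _exp_smooth(x: Tensor, d: Tensor, length: int) -> Tensor:
    """Causal normalized exponential smoothing with per-unit learnable rate.

    The time constant is tau = 1 + d**2 (always >= 1 step); the kernel is the
    truncated normalized exponential exp(-l/tau), so its DC gain is exactly 1.
    ``x`` is (U, T); ``d`` is (U,).
    """
    U = x.shape[0]
    tau = d * d + 1.0
    lags_rev = np.arange(length - 1, -1, -1, dtype=float)  # oldest first
    powers = (Tensor(-lags_rev) / tau.reshape(U, 1)).exp()  # (U, length)
    kernel_rev = powers / powers.sum(axis=1, keepdims=True)
    windows = x.pad_left_replicate(length - 1).unfold(length)  # (U, T, length)
    return einsum("utk,uk->ut", windows, kernel_rev)


class _ModelBase:
    """Shared plumbing: prefilter application, parameter lists, prediction."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.prefilter_layer = None
        self._fixed_params = None
        if config.prefilter in ("adaptrans", "adaptrans_plus_raw"):
            self.prefilter_layer = AdapTransLayer(config.band_freqs, config.dt)
        elif config.prefilter == "ic_adaptation":
            self._fixed_params = AdapTransParams.from_frequencies(
                config.band_freqs, config.dt, trainable=False)
        self._ic_cache = {}

    # subclasses append to this
    def parameters(self):
        return list(self.prefilter_layer.parameters()) if self.prefilter_layer else []

    def n_parameters(self):
        return sum(p.data.size for p in self.parameters())

    def input_channels(self, cochleagram) -> Tensor:
        """Map a cochleagram to the (C, F, T) backbone input."""
        values = np.asarray(cochleagram.values, dtype=float)
        mode = self.config.prefilter
        if mode == "none":
            return Tensor(values[None])
        if mode == "ic_adaptation":
            key = id(cochleagram)
            if key not in self._ic_cache:
                self._ic_cache[key] = ic_adaptation(cochleagram, self._fixed_params)
            return Tensor(self._ic_cache[key][None])
        polar = relu(self.prefilter_layer.forward(Tensor(values)))
        if mode == "adaptrans":
            return polar
        return concatenate([polar, Tensor(values[None])], axis=0)

    def forward(self, cochleagram, training=False) -> Tensor:
        raise NotImplementedError

    def predict(self, cochleagram) -> np.ndarray:
        """Predicted response(s), shape (T,) for single-unit or (N, T)."""
        out = self.forward(cochleagram, training=False).data
        return out[0] if self.config.n_outputs == 1 else out

    def state_arrays(self) -> dict:
        """Named parameter (and BN running-stat) arrays for checkpointing."""
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        for j, bn in enumerate(getattr(self, "_bns", [])):
            arrays[f"bn{j}_mean"] = bn.running_mean
            arrays[f"bn{j}_var"] = bn.running_var
        return arrays

    def load_state_arrays(self, arrays: dict):
        for i, p in enumerate(self.parameters()):
            p.data = np.array(arrays[f"param_{i}"], dtype=float)
        for j, bn in enumerate(getattr(self, "_bns", [])):
            bn.running_mean = np.array(arrays[f"bn{j}_mean"], dtype=float)
            bn.running_var = np.array(arrays[f"bn{j}_var"], dtype=float)

    def clone_state(self):
        return copy.deepcopy(self.state_arrays())


class LinearModel(_ModelBase):
    """The canonical linear (STRF) model: causal spectro-temporal projection
    plus a bias.  Optionally batch-normalized (affine-free) after the STRF."""

    backbone = "L"

    def __init__(self, config: ModelConfig, rng=None):
        super().__init__(config)
        rng = np.random.default_rng(rng)
        C, F, L, N = config.channels, config.F, config.T, config.n_outputs
        scale = 1.0 / np.sqrt(C * F * L)
        # reversed-time layout: last lag index is the present sample
        self.weights = Tensor(rng.normal(0, scale, (N, C, F, L)), requires_grad=True)
        self.bias = Tensor(np.zeros(N), requires_grad=True)
        self._bns = []
        if config.use_batchnorm and config.backbone == "L" and getattr(
                config, "l_batchnorm", False):
            self._bns = [BatchNorm(N, affine=False)]

    @property
    def strf(self) -> np.ndarray:
        """STRF weights in lag orientation (N, C, F, lag), lag 0 = present."""
        return self.weights.data[..., ::-1].copy()

    def set_strf(self, strf):
        strf = np.asarray(strf, dtype=float)
        self.weights.data = strf[..., ::-1].copy()

    def parameters(self):
        ps = super().parameters() + [self.weights, self.bias]
        for bn in self._bns:
            ps += bn.parameters()
        return ps

    def _linear_out(self, cochleagram, training):
        x = self.input_channels(cochleagram)
        y = _causal_conv_full_band(x, self.weights, self.config.T)
        return y + self.bias.reshape(self.config.n_outputs, 1)

    def forward(self, cochleagram, training=False):
        y = self._linear_out(cochleagram, training)
        if self._bns:
            y = self._bns[0].forward(y, training)
        return y


class LNModel(LinearModel):
    """Linear-nonlinear model: STRF -> batch normalization -> sigmoid.

    The normalization (affine-free) sits between the STRF and the output
    nonlinearity in all conditions; output lies in (0, 1).
    """

    backbone = "LN"

    def __init__(self, config: ModelConfig, rng=None):
        super().__init__(config, rng)
        self._bns = [BatchNorm(config.n_outputs, affine=False)] if config.use_batchnorm else []

    def forward(self, cochleagram, training=False):
        y = self._linear_out(cochleagram, training)
        if self._bns:
            y = self._bns[0].forward(y, training)
        return sigmoid(y)


class NRFModel(_ModelBase):
    """Network receptive field: H parallel STRFs -> BN -> sigmoid -> linear
    readout (no output nonlinearity)."""

    backbone = "NRF"

    def __init__(self, config: ModelConfig, rng=None):
        super().__init__(config)
        rng = np.random.default_rng(rng)
        C, F, L, H, N = (config.channels, config.F, config.T, config.H,
                         config.n_outputs)
        scale = 1.0 / np.sqrt(C * F * L)
        self.weights = Tensor(rng.normal(0, scale, (H, C, F, L)), requires_grad=True)
        self.hidden_bias = Tensor(np.zeros(H), requires_grad=True)
        self.bn = BatchNorm(H, affine=True)
        self._bns = [self.bn]
        self.readout = Tensor(rng.normal(0, 1.0 / np.sqrt(H), (N, H)),
                              requires_grad=True)
        self.out_bias = Tensor(np.zeros(N), requires_grad=True)

    def parameters(self):
        return (super().parameters() + [self.weights, self.hidden_bias]
                + self.bn.parameters() + [self.readout, self.out_bias])

    def hidden(self, cochleagram, training):
        x = self.input_channels(cochleagram)
        h = _causal_conv_full_band(x, self.weights, self.config.T)
        h = h + self.hidden_bias.reshape(self.config.H, 1)
        return sigmoid(self.bn.forward(h, training))

    def forward(self, cochleagram, training=False):
        h = self.hidden(cochleagram, training)
        return self.readout @ h + self.out_bias.reshape(self.config.n_outputs, 1)


class DNetModel(_ModelBase):
    """Dynamic network: short STRFs whose hidden and output units follow a
    leaky (exponentially smoothed) dynamic with learnable per-unit time
    constants tau = 1 + d**2."""

    backbone = "DNet"

    def __init__(self, config: ModelConfig, rng=None):
        super().__init__(config)
        rng = np.random.default_rng(rng)
        C, F, L, H, N = (config.channels, config.F, config.T, config.H,
                         config.n_outputs)
        scale = 1.0 / np.sqrt(C * F * L)
        self.weights = Tensor(rng.normal(0, scale, (H, C, F, L)), requires_grad=True)
        self.hidden_bias = Tensor(np.zeros(H), requires_grad=True)
        self.bn = BatchNorm(H, affine=True)
        self._bns = [self.bn]
        self.d_hidden = Tensor(rng.normal(0, 0.5, H), requires_grad=True)
        self.readout = Tensor(rng.normal(0, 1.0 / np.sqrt(H), (N, H)),
                              requires_grad=True)
        self.out_bias = Tensor(np.zeros(N), requires_grad=True)
        self.d_out = Tensor(rng.normal(0, 0.5, N), requires_grad=True)

    def parameters(self):
        return (super().parameters() + [self.weights, self.hidden_bias]
                + self.bn.parameters()
                + [self.d_hidden, self.readout, self.out_bias, self.d_out])

    @property
    def hidden_taus(self):
        return 1.0 + self.d_hidden.data ** 2

    def forward(self, cochleagram, training=False):
        cfg = self.config
        x = self.input_channels(cochleagram)
        h = _causal_conv_full_band(x, self.weights, cfg.T)
        h = h + self.hidden_bias.reshape(cfg.H, 1)
        h = self.bn.forward(h, training)
        h = _exp_smooth(h, self.d_hidden, cfg.smooth_len)
        h = sigmoid(h)
        y = self.readout @ h + self.out_bias.reshape(cfg.n_outputs, 1)
        return _exp_smooth(y, self.d_out, cfg.smooth_len)


class CNN2DModel(_ModelBase):
    """Three 2-D convolutions (BN + LeakyReLU 0.1 after each, causal in time,
    valid in frequency) followed by a two-layer fully connected head applied
    at every time bin."""

    backbone = "CNN2D"

    def __init__(self, config: ModelConfig, rng=None):
        super().__init__(config)
        rng = np.random.default_rng(rng)
        C, Fk, Tk = config.channels, config.F_kernel, config.T
        ch, fc, N = config.cnn_channels, config.cnn_fc, config.n_outputs
        self.f_out = _cnn_freq_out(config.n_bands_in, Fk)
        self.conv_w, self.conv_b = [], []
        c_in = C
        for _ in range(3):
            scale = 1.0 / np.sqrt(c_in * Fk * Tk)
            self.conv_w.append(Tensor(rng.normal(0, scale, (ch, c_in, Fk, Tk)),
                                      requires_grad=True))
            self.conv_b.append(Tensor(np.zeros(ch), requires_grad=True))
            c_in = ch
        self._bns = [BatchNorm(ch, affine=True) for _ in range(3)]
        self.fc1_w = Tensor(rng.normal(0, 1.0 / np.sqrt(ch * self.f_out),
                                       (fc, ch * self.f_out)), requires_grad=True)
        self.fc1_b = Tensor(np.zeros(fc), requires_grad=True)
        self.fc2_w = Tensor(rng.normal(0, 1.0 / np.sqrt(fc), (N, fc)),
                            requires_grad=True)
        self.fc2_b = Tensor(np.zeros(N), requires_grad=True)

    def parameters(self):
        ps = super().parameters()
        for w, b, bn in zip(self.conv_w, self.conv_b, self._bns):
            ps += [w, b] + bn.parameters()
        return ps + [self.fc1_w, self.fc1_b, self.fc2_w, self.fc2_b]

    @staticmethod
    def _conv2d(x: Tensor, w_rev: Tensor, bias: Tensor, f_kernel: int,
                t_kernel: int) -> Tensor:
        """Causal-time, valid-frequency 2-D convolution.

        ``x`` is (C, F, T); ``w_rev`` is (O, C, Fk, Tk) in reversed-time
        layout.  Returns (O, F - Fk + 1, T).
        """
        win_t = x.pad_left_replicate(t_kernel - 1).unfold(t_kernel)  # (C,F,T,Tk)
        win_t = win_t.transpose((0, 3, 2, 1))                        # (C,Tk,T,F)
        win = win_t.unfold(f_kernel)                                 # (C,Tk,T,Fo,Fk)
        out = einsum("cktfg,ocgk->oft", win, w_rev)
        return out + bias.reshape(-1, 1, 1)

    def forward(self, cochleagram, training=False):
        cfg = self.config
        x = self.input_channels(cochleagram)
        for w, b, bn in zip(self.conv_w, self.conv_b, self._bns):
            x = self._conv2d(x, w, b, cfg.F_kernel, cfg.T)
            x = leaky_relu(bn.forward(x, training), 0.1)
        ch, f_out = cfg.cnn_channels, self.f_out
        T = x.shape[-1]
        flat = x.reshape(ch * f_out, T)
        h = leaky_relu(self.fc1_w @ flat + self.fc1_b.reshape(-1, 1), 0.1)
        return self.fc2_w @ h + self.fc2_b.reshape(cfg.n_outputs, 1)


# For the CNN, Table-style configs give the conv kernel span as (F, T) and the
# actual number of input bands separately.
@dataclass
class CNNConfig(ModelConfig):
    """CNN2D configuration: ``F`` and ``T`` are the per-layer conv kernel
    spans (frequency, time); ``n_bands_in`` is the cochleagram band count."""

    n_bands_in: int = 18

    def __post_init__(self):
        self.backbone = "CNN2D"
        super().__post_init__()

    @property
    def n_bands(self):
        return self.n_bands_in

    @property
    def F_kernel(self):
        return self.F

    @property
    def n_freq_out(self):
        return _cnn_freq_out(self.n_bands_in, self.F_kernel)


_BUILDERS = {"L": LinearModel, "LN": LNModel, "NRF": NRFModel, "DNet": DNetModel,
             "CNN2D": CNN2DModel}


def build_model(config: ModelConfig, rng=None) -> _ModelBase:
    """Instantiate the configured backbone (seeded weight initialization)."""
    return _BUILDERS[config.backbone](config, rng=rng)


def count_model_parameters(model: _ModelBase) -> int:
    """Parameter count of an instantiated model (cross-check for budgets)."""
    return model.n_parameters()


def save_checkpoint(model: _ModelBase, path):
    """Single-file archive: config (JSON) + named parameter arrays."""
    cfg = asdict(model.config)
    cfg["band_freqs"] = model.config.band_freqs.tolist()
    arrays = model.state_arrays()
    np.savez(path, __config__=json.dumps(cfg, default=float), **arrays)


def load_checkpoint(path) -> _ModelBase:
    with np.load(path, allow_pickle=False) as f:
        cfg = json.loads(str(f["__config__"]))
        cfg["band_freqs"] = np.asarray(cfg["band_freqs"], dtype=float)
        cls = CNNConfig if "n_bands_in" in cfg else ModelConfig
        model = build_model(cls(**cfg))
        model.load_state_arrays({k: f[k] for k in f.files if k != "__config__"})
    return model


def strf_to_csv(model: LinearModel, path):
    """Dump STRF weights as CSV (unit, channel, band, lag, weight)."""
    import pandas as pd

    strf = model.strf
    N, C, F, L = strf.shape
    n, c, f, l = np.meshgrid(range(N), range(C), range(F), range(L), indexing="ij")
    pd.DataFrame({"unit": n.ravel(), "channel": c.ravel(), "band": f.ravel(),
                  "lag": l.ravel(), "weight": strf.ravel()}).to_csv(path, index=False)
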