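"""Reproducible simulation experiments: ramp/step OFF-response curves, the
three-band offset model, the parameter-budget table, and teacher-recovery
studies.  Every experiment is deterministic given its seed and returns plain
tables (DataFrames / dicts) that the CLI can serialize.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (NeuralClip, TeacherSpec, make_fall_ramp,
                   make_multiband_binary, make_random_binary, make_step,
                   simulate_teacher_responses)
from .filters import (AdapTransParams, apply_adaptrans,
                      offset_amplitude_closed_form)
from .models import CNNConfig, ModelConfig, build_model, count_parameters
from .training import (FitProtocol, SplitSpec, evaluate, fit,
                       recover_parameters, split_clips)

__all__ = [
    "exp_fallramp",
    "exp_step_duration",
    "exp_multiband",
    "exp_param_table",
    "exp_recovery",
    "fit_offset_curve",
    "PUBLISHED_PARAM_BUDGETS",
]


def _single_band_params(w, a_off, dt=0.001, a_on=None):
    a_on = a_off if a_on is None else a_on
    return AdapTransParams(w=[w], a_on=[a_on], a_off=[a_off], dt=dt,
                           band_freqs=[1000.0])


def exp_fallramp(a_off=0.99, w=0.75, ramp_lengths=None, dt=0.001,
                 plateau_len=500) -> pd.DataFrame:
    """OFF-channel peak amplitude and latency versus fall-ramp duration.

    For each ramp length, a unit plateau followed by a linear descent is
    filtered with the OFF kernel; the peak after ramp start and its timing
    are recorded.  Abrupt offsets elicit the largest, earliest peaks: the
    peak decreases and the latency is non-decreasing as the ramp lengthens.
    """
    if ramp_lengths is None:
        ramp_lengths = np.unique(np.geomspace(1, 400, 20).astype(int))
    params = _single_band_params(w, a_off, dt)
    # generous truncation (25 tau): the finite-sum renormalization then
    # differs from the infinite-kernel normalizer by ~e-25, so simulated
    # peaks match the untruncated filter to well below 1e-6
    K = int(25 * max(params.tau_on.max(), params.tau_off.max())) + 1
    rows = []
    for ramp in ramp_lengths:
        T = 1 + plateau_len + int(ramp) + K + 10
        # one silent bin before the plateau so the sound has a true onset
        stim = make_fall_ramp(1, T, plateau_len, int(ramp), dt=dt,
                              band_freqs=[1000.0], onset=1)
        off = apply_adaptrans(stim, params, K=K).off[0]
        seg = off[1 + plateau_len:]
        peak_idx = int(np.argmax(seg))
        rows.append({"ramp_len_steps": int(ramp),
                     "ramp_len_s": ramp * dt,
                     "off_peak": float(seg[peak_idx]),
                     "off_latency_steps": peak_idx,
                     "off_latency_s": peak_idx * dt})
    return pd.DataFrame(rows)


def exp_step_duration(a=0.99, durations=None, dt=0.001, w=0.75) -> pd.DataFrame:
    """OFF peak at step termination versus step duration, simulated and
    closed form (1 - a**T); the two agree to numerical precision when the
    kernel support covers the step."""
    if durations is None:
        durations = np.unique(np.geomspace(1, 500, 25).astype(int))
    params = _single_band_params(w, a, dt)
    rows = []
    # K covers the whole step AND makes the truncation renormalization
    # negligible (a**(K-1) < 1e-9), emulating the untruncated kernel
    K_untrunc = int(np.ceil(np.log(1e-9) / np.log(a))) + 2
    for T_step in durations:
        T_step = int(T_step)
        K = max(T_step + 2, K_untrunc)
        T = T_step + 11
        # silence before the onset: the preceding-sound duration is T_step
        stim = make_step(1, T, 1, 1 + T_step, dt=dt, band_freqs=[1000.0])
        off = apply_adaptrans(stim, params, K=K).off[0]
        simulated = float(off[1 + T_step])  # first bin after termination
        closed = float(offset_amplitude_closed_form(T_step, a))
        rows.append({"duration_steps": T_step, "duration_s": T_step * dt,
                     "simulated_peak": simulated, "closed_form_peak": closed})
    return pd.DataFrame(rows)


@dataclass
class MultibandResult:
    readout_true: np.ndarray
    readout_fitted: np.ndarray
    readout_lstsq: np.ndarray
    bias_true: float
    bias_fitted: float
    final_mse: float
    gradient_max_relative_error: float
    lstsq_max_relative_error: float
    trace_true: np.ndarray
    trace_fitted: np.ndarray
    n_filter_params: int = 9
    n_readout_params: int = 6


def exp_multiband(seed=0, dt=0.001, sigma=0.0, max_epochs=1500,
                  learning_rate=5e-2) -> MultibandResult:
    """Fit the 15-parameter three-band ON/OFF model to a self-generated trace.

    The stimulus has three bands switching off at 0.3/0.4/0.5 s.  The model is
    per-band paired filtering (9 parameters) -> rectification -> weighted sum
    over the 6 band-polarity channels plus a bias.  The target is generated by
    a teacher with the same filter parameterization.

    Two routes are reported.  The joint gradient fit drives the predicted
    trace onto the target (small final MSE), but the readout it lands on need
    not match the teacher's: the rectified sustained components of the ON and
    OFF channels are nearly collinear with each other and with the bias, so
    the optimum sits in a very flat valley where filter-parameter drift is
    compensated by readout rescaling.  The closed-form least-squares solve on
    the teacher's channels — the identifiability oracle — recovers the readout
    and bias to machine precision, showing the degeneracy is an optimization
    sloppiness, not a property of the model.
    """
    rng = np.random.default_rng(seed)
    stim = make_multiband_binary(dt=dt)
    teacher_params = AdapTransParams.from_frequencies(stim.band_freqs, dt)
    w_true = rng.uniform(0.5, 2.0, size=(2, 3))
    bias_true = 0.1
    teacher = TeacherSpec(params=teacher_params, weights=w_true, bias=bias_true,
                          sigma=sigma, n_repeats=1)
    target = teacher.psth(stim)

    # identifiability oracle: direct least squares on the rectified channels
    from .filters import rectify
    channels = rectify(apply_adaptrans(stim, teacher_params)).values.reshape(6, -1)
    X = np.vstack([channels, np.ones(channels.shape[1])]).T
    sol, *_ = np.linalg.lstsq(X, target, rcond=None)
    readout_lstsq = sol[:6].reshape(2, 3)
    lstsq_rel = np.abs(readout_lstsq - w_true) / np.abs(w_true)

    config = ModelConfig(backbone="L", prefilter="adaptrans", F=3, T=1,
                         dt=dt, band_freqs=stim.band_freqs)
    model = build_model(config, rng=seed)
    clip = NeuralClip(stimulus=stim, trials=target[None, :], clip_id="multiband")
    protocol = FitProtocol(learning_rate=learning_rate, patience=max_epochs,
                           max_epochs=max_epochs, seed=seed)
    result = fit(model, protocol, [clip], [clip])
    fitted = model.strf[0, :, :, 0]  # (2, 3) readout over (polarity, band)
    rel_err = np.abs(fitted - w_true) / np.abs(w_true)
    return MultibandResult(
        readout_true=w_true, readout_fitted=fitted, readout_lstsq=readout_lstsq,
        bias_true=bias_true, bias_fitted=float(model.bias.data[0]),
        final_mse=result.best_val_loss,
        gradient_max_relative_error=float(rel_err.max()),
        lstsq_max_relative_error=float(lstsq_rel.max()),
        trace_true=target, trace_fitted=model.predict(stim))


# Published per-dataset parameter budgets used as a verification oracle.
# Keys: (backbone, prefilter-kind, dataset). "control" covers both the raw and
# the fixed single-channel adaptation prefilters (same budgets).  Cells with
# known ambiguity are marked excluded and reported but not asserted.
_GEOM = {
    "NS1": dict(dt=0.005, F=34, T=41, T_dnet=5, cnn=(6, 15)),
    "Wehr": dict(dt=0.005, F=49, T=21, T_dnet=5, cnn=(7, 6)),
    "NAT4": dict(dt=0.010, F=18, T=21, T_dnet=5, cnn=(3, 7)),
}

PUBLISHED_PARAM_BUDGETS = {
    ("L", "control", "NS1"): (1395, False), ("L", "adaptrans", "NS1"): (2891, False),
    ("L", "control", "Wehr"): (1030, False), ("L", "adaptrans", "Wehr"): (2206, False),
    ("L", "control", "NAT4"): (379, False), ("L", "adaptrans", "NAT4"): (811, False),
    ("LN", "control", "NS1"): (1395, False), ("LN", "adaptrans", "NS1"): (2891, False),
    ("LN", "control", "Wehr"): (1030, False), ("LN", "adaptrans", "Wehr"): (2206, False),
    ("LN", "control", "NAT4"): (379, False), ("LN", "adaptrans", "NAT4"): (811, False),
    ("NRF", "control", "NS1"): (27961, False), ("NRF", "adaptrans", "NS1"): (28023, False),
    ("NRF", "control", "Wehr"): (20661, False), ("NRF", "adaptrans", "Wehr"): (20768, False),
    ("NRF", "control", "NAT4"): (7641, False), ("NRF", "adaptrans", "NAT4"): (7655, False),
    ("DNet", "control", "NS1"): (3502, False), ("DNet", "adaptrans", "NS1"): (3552, True),
    ("DNet", "control", "Wehr"): (5002, False), ("DNet", "adaptrans", "Wehr"): (5099, False),
    ("DNet", "control", "NAT4"): (1902, False), ("DNet", "adaptrans", "NAT4"): (1906, False),
    ("CNN2D", "control", "NS1"): (36274, True), ("CNN2D", "adaptrans", "NS1"): (37276, True),
    ("CNN2D", "control", "Wehr"): (39694, True), ("CNN2D", "adaptrans", "Wehr"): (40261, True),
    ("CNN2D", "control", "NAT4"): (15484, True), ("CNN2D", "adaptrans", "NAT4"): (15748, True),
}


def published_geometry(backbone, prefilter, dataset) -> ModelConfig:
    """Model geometry for a published (backbone, prefilter, dataset) cell.

    The hidden width of NRF/DNet is halved under the paired prefilter so that
    total budgets stay level with their single-channel controls.
    """
    g = _GEOM[dataset]
    adap = prefilter in ("adaptrans", "adaptrans_plus_raw")
    if backbone == "CNN2D":
        fk, tk = g["cnn"]
        return CNNConfig(prefilter=prefilter, F=fk, T=tk,
                         n_bands_in=g["F"], dt=g["dt"])
    T = g["T_dnet"] if backbone == "DNet" else g["T"]
    H = 1 if backbone in ("L", "LN") else (10 if adap else 20)
    return ModelConfig(backbone=backbone, prefilter=prefilter, F=g["F"], T=T,
                       H=H, dt=g["dt"])


def exp_param_table() -> pd.DataFrame:
    """Compute every budget cell and compare with the published values.

    Cells flagged as excluded (CNN architecture ambiguity; one probable typo
    in the NS1 DNet cell) are reported but not held to equality.
    """
    rows = []
    for (backbone, kind, dataset), (published, excluded) in \
            PUBLISHED_PARAM_BUDGETS.items():
        prefilter = "adaptrans" if kind == "adaptrans" else "none"
        config = published_geometry(backbone, prefilter, dataset)
        computed = count_parameters(config)
        rows.append({"backbone": backbone, "prefilter": kind, "dataset": dataset,
                     "computed": computed, "published": published,
                     "excluded": excluded,
                     "match": (computed == published) or excluded})
    return pd.DataFrame(rows)


@dataclass
class RecoveryResult:
    noise_levels: list
    records: list = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def make_teacher_set(seed=0, F=16, T=500, n_clips=20, n_repeats=10,
                     sigma=0.05, dt=0.005, p_switch=0.02):
    """Standard teacher fixture: random telegraph stimuli driving a neuron
    with frequency-rule time constants, per-band w drawn in [0.3, 0.9], and a
    positive random readout over the rectified ON/OFF channels."""
    rng = np.random.default_rng(seed)
    band_freqs = np.geomspace(500.0, 22627.0, F)
    params = AdapTransParams.from_frequencies(band_freqs, dt)
    params.w = rng.uniform(0.3, 0.9, F)
    weights = rng.uniform(0.2, 1.0, (2, F)) / F
    teacher = TeacherSpec(params=params, weights=weights, bias=0.05,
                          sigma=sigma, n_repeats=n_repeats)
    stimuli = [make_random_binary(F, T, rng, p_switch=p_switch, dt=dt,
                                  band_freqs=band_freqs)
               for _ in range(n_clips)]
    rec = simulate_teacher_responses(teacher, stimuli, seed=seed + 1)
    return teacher, rec


def exp_recovery(seed=0, noise_levels=(0.0, 0.05, 0.2), F=16, T=500,
                 n_clips=20, n_repeats=10, backbones=("L",),
                 lags=5, max_epochs=500, patience=50) -> RecoveryResult:
    """Teacher-recovery study across noise levels.

    For each noise level, fits backbones with the learnable paired prefilter
    and a raw-spectrogram control on the same synthetic data, and reports
    held-out CC_raw/CC_norm plus filter-parameter recovery errors.
    """
    result = RecoveryResult(noise_levels=list(noise_levels))
    for sigma in noise_levels:
        teacher, rec = make_teacher_set(seed=seed, F=F, T=T, n_clips=n_clips,
                                        n_repeats=n_repeats, sigma=sigma)
        train, val, test = split_clips(rec, SplitSpec(), seed)
        protocol = FitProtocol(seed=seed, max_epochs=max_epochs,
                               patience=patience)
        for backbone in backbones:
            for prefilter in ("adaptrans", "none"):
                config = ModelConfig(backbone=backbone, prefilter=prefilter,
                                     F=F, T=lags, H=10, dt=rec.dt,
                                     band_freqs=rec.band_freqs)
                model = build_model(config, rng=seed)
                fit(model, protocol, train, val)
                record = evaluate(model, test)
                record.update({"sigma": sigma, "backbone": backbone,
                               "prefilter": prefilter})
                if prefilter == "adaptrans":
                    rep = recover_parameters(teacher, model)
                    record["w_median_abs_error"] = rep["w_median_abs_error"]
                    record["w_rank_correlation"] = rep["w_rank_correlation"]
                result.records.append(record)
    return result


def fit_offset_curve(x, amplitude, kind="duration", dt=0.001, p0=None):
    """Fit the offset-amplitude law to user-supplied (x, amplitude) points.

    ``kind='duration'`` fits gain * (1 - a**(x/dt)) over preceding-sound
    duration x (seconds); ``kind='ramp'`` fits the simulated ramp-peak curve
    over fall-ramp duration.  Returns the optimal (a, gain) and the fitted
    curve.  Intended for digitized experimental measurements supplied as CSV;
    none are bundled.
    """
    from scipy.optimize import curve_fit

    x = np.asarray(x, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)

    if kind == "duration":
        def f(x_s, a, gain):
            return gain * (1.0 - a ** (x_s / dt))
    elif kind == "ramp":
        def f(x_s, a, gain):
            peaks = []
            for xs in np.atleast_1d(x_s):
                ramp = max(int(round(xs / dt)), 1)
                tab = exp_fallramp(a_off=a, ramp_lengths=[ramp], dt=dt)
                peaks.append(tab["off_peak"].iloc[0])
            return gain * np.asarray(peaks)
    else:
        raise ValueError("kind must be 'duration' or 'ramp'")
    p0 = p0 or (0.99, float(amplitude.max()) or 1.0)
    popt, _ = curve_fit(f, x, amplitude, p0=p0,
                        bounds=([1e-6, 1e-9], [1 - 1e-9, np.inf]))
    return {"a": float(popt[0]), "gain": float(popt[1]),
            "fitted": f(x, *popt), "r2": 1.0 - np.sum((amplitude - f(x, *popt)) ** 2)
                                          / np.sum((amplitude - amplitude.mean()) ** 2)}
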