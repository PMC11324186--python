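"""Stimulus/response containers, synthetic generators, preprocessing and I/O.

Real recordings (ferret/rat cortical datasets) are supported through a simple
HDF5 container, but nothing here requires them: the module can generate the
test stimuli used in the simulation experiments (steps, fall ramps, the
three-band offset stimulus) and full synthetic recording sets from a "teacher"
neuron (ON/OFF filter -> rectify -> linear readout -> trial noise) that mimic
the clip/trial structure of real sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .filters import AdapTransParams, apply_adaptrans, rectify

__all__ = [
    "Cochleagram",
    "NeuralClip",
    "RecordingSet",
    "TeacherSpec",
    "make_step",
    "make_fall_ramp",
    "make_multiband_binary",
    "make_random_binary",
    "log_stft_cochleagram",
    "detrend_linear",
    "drop_null_psth_pairs",
    "simulate_teacher_responses",
    "write_recording_hdf5",
    "read_recording_hdf5",
    "psth_to_csv",
]


@dataclass
class Cochleagram:
    """F x T log-compressed spectro-temporal stimulus representation."""

    values: np.ndarray
    band_freqs: np.ndarray
    dt: float

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.band_freqs = np.atleast_1d(np.asarray(self.band_freqs, dtype=float))
        if self.values.shape[0] != len(self.band_freqs):
            raise ValueError("number of rows must equal number of band frequencies")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if len(self.band_freqs) > 1 and np.any(np.diff(self.band_freqs) <= 0):
            raise ValueError("band frequencies must be strictly increasing")

    @property
    def n_bands(self):
        return self.values.shape[0]

    @property
    def n_times(self):
        return self.values.shape[1]


@dataclass
class NeuralClip:
    """One stimulus clip with its N x T repeated-trial responses."""

    stimulus: Cochleagram
    trials: np.ndarray
    unit_id: str = "unit0"
    clip_id: str = "clip0"

    def __post_init__(self):
        self.trials = np.atleast_2d(np.asarray(self.trials, dtype=float))
        if self.trials.shape[1] != self.stimulus.n_times:
            raise ValueError("trials and stimulus must share the time axis")
        if self.trials.shape[0] < 1:
            raise ValueError("need at least one trial")

    @property
    def n_trials(self):
        return self.trials.shape[0]


@dataclass
class RecordingSet:
    """A list of clips with uniform geometry plus unit metadata."""

    clips: list
    dt: float
    tag: str = "synthetic"
    area: str = "synthetic"
    species: str = "synthetic"
    kind: str = "spikes"  # spikes | potential
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.clips:
            F = self.clips[0].stimulus.n_bands
            for c in self.clips:
                if c.stimulus.n_bands != F:
                    raise ValueError("all clips must share the band count")
                if abs(c.stimulus.dt - self.dt) > 1e-12:
                    raise ValueError("all clips must share dt")

    def __len__(self):
        return len(self.clips)

    def __iter__(self):
        return iter(self.clips)

    @property
    def band_freqs(self):
        return self.clips[0].stimulus.band_freqs


def _band_grid(F, f_lo=500.0, f_hi=22627.0):
    """Logarithmically spaced band centers (Hz), the usual cochleagram layout."""
    if F == 1:
        return np.array([f_lo])
    return np.geomspace(f_lo, f_hi, F)


def make_step(F, T, onset, offset, amplitude=1.0, dt=0.005, band_freqs=None) -> Cochleagram:
    """Binary step stimulus: every band is ``amplitude`` on [onset, offset)."""
    if not (0 <= onset < offset <= T):
        raise ValueError(f"need 0 <= onset < offset <= T, got {onset}, {offset}, {T}")
    values = np.zeros((F, T))
    values[:, onset:offset] = amplitude
    if band_freqs is None:
        band_freqs = _band_grid(F)
    return Cochleagram(values=values, band_freqs=band_freqs, dt=dt)


def make_fall_ramp(F, T, plateau_len, ramp_len, dt=0.005, band_freqs=None,
                   onset=0) -> Cochleagram:
    """Unit plateau followed by a linear descent to 0 over ``ramp_len`` steps.

    ``ramp_len = 1`` is the abrupt-offset limiting case and equals
    :func:`make_step` of the same plateau.  ``onset`` bins of silence may
    precede the plateau (with replicate padding, a stimulus that is already
    on at its first bin is treated as on for all past time).
    """
    if plateau_len < 1 or ramp_len < 1 or onset < 0 \
            or onset + plateau_len + ramp_len > T:
        raise ValueError("need plateau_len, ramp_len >= 1 and "
                         "onset + plateau_len + ramp_len <= T")
    env = np.zeros(T)
    env[onset:onset + plateau_len] = 1.0
    # linear descent: ramp_len samples strictly between 1 and 0
    ramp = 1.0 - np.arange(1, ramp_len + 1) / float(ramp_len)
    env[onset + plateau_len:onset + plateau_len + ramp_len] = ramp
    if band_freqs is None:
        band_freqs = _band_grid(F)
    return Cochleagram(values=np.tile(env, (F, 1)), band_freqs=band_freqs, dt=dt)


def make_multiband_binary(dt=0.001, band_offsets_s=(0.3, 0.4, 0.5), T=None,
                          band_freqs=None) -> Cochleagram:
    """Three-band binary stimulus whose bands switch off at distinct instants.

    Default offsets 0.3, 0.4 and 0.5 s at dt = 1 ms: each band is 1 from t = 0
    until its own offset, then 0, so OFF events are separated across bands.
    """
    offsets = np.asarray(band_offsets_s, dtype=float)
    idx = np.round(offsets / dt).astype(int)
    if T is None:
        T = int(idx.max() + round(0.2 / dt))
    values = np.zeros((len(offsets), T))
    for b, i in enumerate(idx):
        values[b, :i] = 1.0
    if band_freqs is None:
        band_freqs = _band_grid(len(offsets), 1000.0, 8000.0)
    return Cochleagram(values=values, band_freqs=band_freqs, dt=dt)


def make_random_binary(F, T, rng, p_switch=0.02, dt=0.005, band_freqs=None) -> Cochleagram:
    """Random per-band binary telegraph stimulus (independent switching).

    Each band holds a 0/1 level and toggles with probability ``p_switch`` per
    bin, giving every band its own onsets and offsets — the property that makes
    teacher-parameter recovery identifiable.
    """
    rng = np.random.default_rng(rng)
    switches = rng.random((F, T)) < p_switch
    start = rng.integers(0, 2, size=(F, 1))
    values = (np.cumsum(switches, axis=1) + start) % 2
    if band_freqs is None:
        band_freqs = _band_grid(F)
    return Cochleagram(values=values.astype(float), band_freqs=band_freqs, dt=dt)


def log_stft_cochleagram(waveform, sample_rate, n_bands=32, window_s=0.010,
                         hop_s=0.005, f_lo=500.0, f_hi=None, floor_db=-60.0) -> Cochleagram:
    """Minimal waveform-to-cochleagram front end: magnitude STFT pooled into
    log-spaced bands, log-compressed with a floor threshold.

    A deliberately simple stand-in for the gammatone/mel front ends that real
    datasets ship with; adequate for plumbing audio into the pipeline.
    """
    from scipy.signal import stft

    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim != 1 or waveform.size == 0:
        raise ValueError("waveform must be a non-empty mono signal")
    nperseg = max(int(round(window_s * sample_rate)), 2)
    hop = max(int(round(hop_s * sample_rate)), 1)
    freqs, _, Z = stft(waveform, fs=sample_rate, nperseg=nperseg,
                       noverlap=nperseg - hop, boundary=None, padded=True)
    mag = np.abs(Z)
    if f_hi is None:
        f_hi = sample_rate / 2.0 * 0.95
    edges = np.geomspace(f_lo, f_hi, n_bands + 1)
    centers = np.sqrt(edges[:-1] * edges[1:])
    pooled = np.zeros((n_bands, mag.shape[1]))
    for b in range(n_bands):
        sel = (freqs >= edges[b]) & (freqs < edges[b + 1])
        if sel.any():
            pooled[b] = mag[sel].mean(axis=0)
    with np.errstate(divide="ignore"):
        logmag = 20.0 * np.log10(pooled)
    values = np.maximum(logmag, floor_db)
    return Cochleagram(values=values, band_freqs=centers, dt=hop / sample_rate)


def detrend_linear(trials):
    """Remove the per-trial best-fit line over time (drift removal for
    membrane-potential recordings).  Idempotent to numerical precision."""
    from scipy.signal import detrend

    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    return detrend(trials, axis=1, type="linear")


def drop_null_psth_pairs(rec: RecordingSet) -> RecordingSet:
    """Remove clips whose trials are identically zero (no spike in any trial)."""
    kept = [c for c in rec.clips if np.any(c.trials != 0)]
    return RecordingSet(clips=kept, dt=rec.dt, tag=rec.tag, area=rec.area,
                        species=rec.species, kind=rec.kind, extras=dict(rec.extras))


@dataclass
class TeacherSpec:
    """Ground-truth generative neuron: filter params + linear readout + noise.

    ``weights`` has shape (2, F): one weight per (polarity, band) of the
    rectified polar spectrogram.  Trials are PSTH + i.i.d. Gaussian noise of
    standard deviation ``sigma``.
    """

    params: AdapTransParams
    weights: np.ndarray
    bias: float = 0.0
    sigma: float = 0.05
    n_repeats: int = 10

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (2, self.params.n_bands):
            raise ValueError("weights must have shape (2, F)")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def psth(self, stimulus: Cochleagram) -> np.ndarray:
        """Noise-free response: bias + sum of weighted rectified ON/OFF channels."""
        polar = rectify(apply_adaptrans(stimulus, self.params))
        return self.bias + np.einsum("cf,cft->t", self.weights, polar.values)


def simulate_teacher_responses(spec: TeacherSpec, stimuli, seed) -> RecordingSet:
    """Generate a deterministic synthetic recording set from a teacher neuron."""
    rng = np.random.default_rng(seed)
    clips = []
    for i, stim in enumerate(stimuli):
        if stim.n_bands != spec.params.n_bands:
            raise ValueError("stimulus band count does not match teacher parameters")
        r = spec.psth(stim)
        noise = rng.normal(0.0, spec.sigma, size=(spec.n_repeats, len(r))) \
            if spec.sigma > 0 else np.zeros((spec.n_repeats, len(r)))
        clips.append(NeuralClip(stimulus=stim, trials=r[None, :] + noise,
                                unit_id="teacher", clip_id=f"clip{i:03d}"))
    return RecordingSet(clips=clips, dt=spec.params.dt, tag="teacher",
                        kind="potential")


_REQUIRED_ATTRS = ("dt", "tag", "area", "species", "kind")


def write_recording_hdf5(rec: RecordingSet, path):
    """Write a RecordingSet to the package's HDF5 container layout."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["dt"] = rec.dt
        f.attrs["tag"] = rec.tag
        f.attrs["area"] = rec.area
        f.attrs["species"] = rec.species
        f.attrs["kind"] = rec.kind
        f.attrs["band_freqs"] = rec.band_freqs
        for c in rec.clips:
            g = f.create_group(f"clips/{c.clip_id}")
            g.create_dataset("cochleagram", data=c.stimulus.values)
            g.create_dataset("trials", data=c.trials)
            g.attrs["unit_id"] = c.unit_id


def read_recording_hdf5(path) -> RecordingSet:
    """Read a RecordingSet back; missing required fields raise a format error
    naming the field."""
    import h5py

    with h5py.File(path, "r") as f:
        for name in _REQUIRED_ATTRS + ("band_freqs",):
            if name not in f.attrs:
                raise KeyError(f"recording file is missing required attribute {name!r}")
        dt = float(f.attrs["dt"])
        band_freqs = np.asarray(f.attrs["band_freqs"], dtype=float)
        clips = []
        for clip_id in sorted(f["clips"]):
            g = f[f"clips/{clip_id}"]
            stim = Cochleagram(values=g["cochleagram"][...],
                               band_freqs=band_freqs, dt=dt)
            clips.append(NeuralClip(stimulus=stim, trials=g["trials"][...],
                                    unit_id=str(g.attrs["unit_id"]), clip_id=clip_id))
        return RecordingSet(clips=clips, dt=dt, tag=str(f.attrs["tag"]),
                            area=str(f.attrs["area"]), species=str(f.attrs["species"]),
                            kind=str(f.attrs["kind"]))


def psth_to_csv(clip: NeuralClip, path):
    """Export one clip's trials and PSTH as CSV (time_s, trial_1..N, psth)."""
    import pandas as pd

    T = clip.stimulus.n_times
    cols = {"time_s": np.arange(T) * clip.stimulus.dt}
    for n in range(clip.n_trials):
        cols[f"trial_{n + 1}"] = clip.trials[n]
    cols["psth"] = clip.trials.mean(axis=0)
    pd.DataFrame(cols).to_csv(path, index=False)


def split_half_partitions(n_trials, cap=126):
    """Deterministic lexicographic half/half partitions of trial indices.

    Yields (half_a, half_b) index tuples with |half_a| = floor(N/2), up to
    ``cap`` distinct partitions; complements are not double-counted for even N.
    """
    k = n_trials // 2
    count = 0
    for comb in itertools.combinations(range(n_trials), k):
        if n_trials % 2 == 0 and comb[0] != 0:
            break  # remaining combinations are complements of earlier ones
        rest = tuple(i for i in range(n_trials) if i not in comb)
        yield comb, rest
        count += 1
        if count >= cap:
            return
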