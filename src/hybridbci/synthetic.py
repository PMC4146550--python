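"""Ground-truth synthetic EEG: every pipeline stage is testable offline.

The generator emulates the signal classes a two-class motor-imagery
session produces on a 16-channel motor montage:

* 1/f (pink) background noise per channel;
* two band-limited oscillatory sources mixed through smooth scalp bumps
  centered on C3 and C4, whose in-band variance drops by ``erd_depth``
  during trials of the matching class (event-related desynchronization)
  and rebounds by ``rebound_gain`` for one second starting 500 ms after
  the trial ends (the beta rebound);
* a slow lateralized ramp of ``-lrp_amplitude`` microvolts from cue onset
  to trial end over the contralateral motor channel (the readiness
  potential), low-frequency by construction;
* optional session drift: the source mixing columns rotate by
  ``drift_rate`` degrees per trial within their common plane, emulating
  the unstable spatial features that motivate classifier adaptation.

No forward head model, no ocular or muscular artifacts: the generator
supports filter/CSP/LDA testing, not physiological realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sig

from .eeg import BandDefinition, Marker, Recording

__all__ = [
    "MONTAGE_16",
    "SyntheticConfig",
    "GroundTruth",
    "generate_recording",
    "generate_screening_recording",
    "scripted_user",
    "pink_noise",
]

#: 16-channel motor montage with planar coordinates (x: left-right,
#: y: anterior-posterior) used for the Gaussian mixing bumps.
MONTAGE_16 = {
    "FC3": (-1.0, 1.0), "FCz": (0.0, 1.0), "FC4": (1.0, 1.0),
    "C5": (-2.0, 0.0), "C3": (-1.0, 0.0), "C1": (-0.5, 0.0),
    "Cz": (0.0, 0.0), "C2": (0.5, 0.0), "C4": (1.0, 0.0), "C6": (2.0, 0.0),
    "CP3": (-1.0, -1.0), "CPz": (0.0, -1.0), "CP4": (1.0, -1.0),
    "P3": (-1.0, -2.0), "Pz": (0.0, -2.0), "P4": (1.0, -2.0),
}


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the generator.

    ``snr`` is the in-band variance ratio of each oscillatory source to
    the background at the source's peak channel; ``erd_depth`` is the
    fractional variance reduction during trials of the matching class.
    """

    seed: int
    n_channels: int = 16
    fs: float = 100.0
    n_trials_per_class: int = 50
    trial_len: float = 5.0
    pause_len: float = 3.0
    erd_band: BandDefinition = field(
        default_factory=lambda: BandDefinition(8.0, 12.0, "alpha")
    )
    erd_depth: float = 0.5
    rebound_gain: float = 1.5
    rebound_delay: float = 0.5
    rebound_len: float = 1.0
    lrp_amplitude: float = 5.0
    snr: float = 1.0
    drift_rate: float = 0.0  # degrees of mixing rotation per trial
    background_std: float = 5.0  # microvolts

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must be in [0, 1]")
        if self.rebound_gain < 1.0:
            raise ValueError("rebound_gain must be >= 1")
        if self.snr < 0:
            raise ValueError("snr must be nonnegative")
        self.erd_band.validate_for_fs(self.fs)


@dataclass
class GroundTruth:
    """What was planted: mixing columns, labels, onsets, effect sizes."""

    mixing: np.ndarray  # channels x 2, initial (undrifted) columns
    labels: np.ndarray  # per-trial class, 1/2
    onsets: np.ndarray  # trial onset samples
    config: SyntheticConfig
    intents: np.ndarray | None = None  # scripted-user intents, if any


def pink_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int
) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spec * shaping, n=n_samples, axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return x


def _gaussian_bump(center: str, labels: list[str], width: float = 0.8):
    cx, cy = MONTAGE_16[center]
    col = np.array(
        [
            np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * width**2))
            for x, y in (MONTAGE_16[l] for l in labels)
        ]
    )
    return col / col.max()


def _rotation_in_plane(a1: np.ndarray, a2: np.ndarray, theta: float) -> np.ndarray:
    """Rotation by *theta* radians in span{a1, a2}, identity elsewhere."""
    u1 = a1 / np.linalg.norm(a1)
    u2 = a2 - (a2 @ u1) * u1
    u2 /= np.linalg.norm(u2)
    n = a1.size
    return (
        np.eye(n)
        + (np.cos(theta) - 1.0) * (np.outer(u1, u1) + np.outer(u2, u2))
        + np.sin(theta) * (np.outer(u2, u1) - np.outer(u1, u2))
    )


def _bandlimited_source(
    rng: np.random.Generator, band: BandDefinition, fs: float, n: int
) -> np.ndarray:
    sos = sig.butter(5, [band.lo, band.hi], btype="band", fs=fs, output="sos")
    x = sig.sosfilt(sos, rng.standard_normal(n))
    return x / x.std()


def generate_recording(
    cfg: SyntheticConfig, labels: np.ndarray | None = None,
    cue_label_map: dict[int, str] | None = None,
) -> tuple[Recording, GroundTruth]:
    """Generate one synthetic session.

    *labels* overrides the balanced shuffled class sequence (used by
    :func:`scripted_user`); *cue_label_map* overrides the marker label
    written for each class (FreeMode streams write "question").
    """
    rng = np.random.default_rng(cfg.seed)
    labels_arr = (
        np.asarray(labels)
        if labels is not None
        else rng.permutation(
            np.r_[
                np.ones(cfg.n_trials_per_class, dtype=int),
                np.full(cfg.n_trials_per_class, 2, dtype=int),
            ]
        )
    )
    n_trials = len(labels_arr)
    fs = cfg.fs
    trial_s = int(round(cfg.trial_len * fs))
    pause_s = int(round(cfg.pause_len * fs))
    lead_in = pause_s
    n_samples = lead_in + n_trials * (trial_s + pause_s) + int(2 * fs)
    onsets = lead_in + np.arange(n_trials) * (trial_s + pause_s)

    channels = list(MONTAGE_16)[: cfg.n_channels]
    if cfg.n_channels > len(MONTAGE_16):
        raise ValueError(f"montage supports at most {len(MONTAGE_16)} channels")
    signal = cfg.background_std * pink_noise(rng, cfg.n_channels, n_samples)

    a1 = _gaussian_bump("C3", channels) if "C3" in channels else None
    a2 = _gaussian_bump("C4", channels) if "C4" in channels else None
    if a1 is None or a2 is None:
        raise ValueError("montage subset must include C3 and C4")
    mixing = np.column_stack([a1, a2])

    sources = np.vstack(
        [
            _bandlimited_source(rng, cfg.erd_band, fs, n_samples)
            for _ in range(2)
        ]
    )
    amp = cfg.background_std * np.sqrt(cfg.snr)

    # class-dependent variance envelopes (ERD during trial, later rebound)
    env = np.ones((2, n_samples))
    reb_off = int(round(cfg.rebound_delay * fs))
    reb_len = int(round(cfg.rebound_len * fs))
    for onset, lab in zip(onsets, labels_arr):
        src = lab - 1
        env[src, onset: onset + trial_s] = np.sqrt(1.0 - cfg.erd_depth)
        r0 = onset + trial_s + reb_off
        env[src, r0: r0 + reb_len] = np.sqrt(cfg.rebound_gain)
    modulated = amp * env * sources

    if cfg.drift_rate != 0.0:
        # piecewise-constant mixing, rotated a bit further every trial
        bounds = np.r_[0, onsets, n_samples]
        for k in range(len(bounds) - 1):
            theta = np.deg2rad(cfg.drift_rate) * k
            A = _rotation_in_plane(a1, a2, theta) @ mixing if theta else mixing
            seg = slice(bounds[k], bounds[k + 1])
            signal[:, seg] += A @ modulated[:, seg]
    else:
        signal += mixing @ modulated

    # lateralized slow ramp on the contralateral motor channel
    idx = {"C3": channels.index("C3"), "C4": channels.index("C4")}
    ramp = np.linspace(0.0, 1.0, trial_s, endpoint=False)
    for onset, lab in zip(onsets, labels_arr):
        ch = idx["C3"] if lab == 1 else idx["C4"]
        signal[ch, onset: onset + trial_s] -= cfg.lrp_amplitude * ramp

    cue_map = cue_label_map or {1: "class1", 2: "class2"}
    markers = []
    for onset, lab in zip(onsets, labels_arr):
        markers.append(Marker(int(onset), cue_map[int(lab)]))
        markers.append(Marker(int(onset + trial_s), "trial_end"))

    rec = Recording(signal=signal, fs=fs, channel_labels=channels,
                    markers=markers)
    gt = GroundTruth(mixing=mixing, labels=labels_arr, onsets=onsets,
                     config=cfg)
    return rec, gt


def generate_screening_recording(
    seed: int,
    fs: float = 100.0,
    segment_len: float = 30.0,
    alpha_amplitude: float = 3.0,
    no_idle_rhythm: bool = False,
    background_std: float = 5.0,
) -> tuple[Recording, dict[str, tuple[int, int]]]:
    """Eyes-open / eyes-closed screening data.

    Eyes-closed carries a 10 Hz posterior idle rhythm (unless
    *no_idle_rhythm*, which emulates the atypical flat resting spectra
    some patients show).  Returns the recording and the condition
    segments as sample ranges.
    """
    rng = np.random.default_rng(seed)
    channels = list(MONTAGE_16)
    seg = int(round(segment_len * fs))
    n = 2 * seg
    signal = background_std * pink_noise(rng, len(channels), n)
    segments = {"eyes-open": (0, seg), "eyes-closed": (seg, n)}
    if not no_idle_rhythm:
        posterior = _gaussian_bump("Pz", channels, width=1.0)
        t = np.arange(seg) / fs
        alpha = np.sin(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))
        # mild amplitude modulation, as real idle rhythms wax and wane
        moddepth = 1.0 + 0.3 * np.sin(2 * np.pi * 0.2 * t)
        signal[:, seg:] += alpha_amplitude * np.outer(posterior, alpha * moddepth)
    return (
        Recording(signal=signal, fs=fs, channel_labels=channels, markers=[]),
        segments,
    )


def drifting_feature_stream(
    seed: int,
    n_train: int = 60,
    n_stream: int = 200,
    dim: int = 4,
    separation: float = 2.0,
    drift_deg_per_trial: float = 0.6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Feature-level nonstationarity: class means rotate during streaming.

    Training features have class means at ``+-separation/2 * u`` along a
    fixed direction ``u`` with unit isotropic covariance; the streamed
    features keep the geometry but the mean axis rotates by
    *drift_deg_per_trial* degrees per trial in the plane of the first two
    dimensions -- the regime where a frozen discriminant decays and an
    adaptive one tracks.  Returns (X_train, y_train, X_stream, y_stream).
    """
    rng = np.random.default_rng(seed)

    def draw(n, angle_per_trial):
        y = rng.integers(1, 3, size=n)
        X = rng.standard_normal((n, dim))
        for i, lab in enumerate(y):
            theta = np.deg2rad(angle_per_trial * i)
            u = np.zeros(dim)
            u[0], u[1] = np.cos(theta), np.sin(theta)
            X[i] += (separation / 2.0) * (1.0 if lab == 2 else -1.0) * u
        return X, y

    X_train, y_train = draw(n_train, 0.0)
    X_stream, y_stream = draw(n_stream, drift_deg_per_trial)
    return X_train, y_train, X_stream, y_stream


def scripted_user(
    intents: np.ndarray | list[int],
    cfg: SyntheticConfig,
    controllability: float = 1.0,
) -> tuple[Recording, GroundTruth]:
    """FreeMode stream from a scripted sequence of intended classes.

    Each trial expresses the intended class's EEG signature with
    probability *controllability* and the opposite class's otherwise
    (a maximally unreliable user at 0.5 conveys no information).  Cues
    are written as "question" markers, as in FreeMode.
    """
    if not 0.0 <= controllability <= 1.0:
        raise ValueError("controllability must be in [0, 1]")
    intents_arr = np.asarray(intents, dtype=int)
    if not np.all(np.isin(intents_arr, (1, 2))):
        raise ValueError("intents must be drawn from {1, 2}")
    rng = np.random.default_rng(cfg.seed + 1)
    flip = rng.random(len(intents_arr)) >= controllability
    expressed = np.where(flip, 3 - intents_arr, intents_arr)
    rec, gt = generate_recording(
        cfg, labels=expressed, cue_label_map={1: "question", 2: "question"}
    )
    gt.intents = intents_arr
    return rec, gt
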