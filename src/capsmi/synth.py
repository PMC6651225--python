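"""Synthetic motor-imagery EEG trials with contralateral ERD.

During imagined hand movement, mu (~10 Hz) and beta (~22 Hz) sensorimotor
rhythms are attenuated (event-related desynchronization, ERD) over the
hemisphere contralateral to the imagined hand: left-hand imagery attenuates
C4, right-hand imagery attenuates C3, and the midline electrode Cz is
unaffected.  This module generates labeled three-channel trials exhibiting
exactly that effect on a white-noise background, so that the whole
filtering / imaging / classification pipeline can be exercised and
validated without any external recordings.

The signal model for each channel is

    x(t) = noise(t) + A_mu * g(t) * sin(2*pi*f_mu*t + phi)
                    + A_beta * g(t) * sin(2*pi*f_beta*t + psi)

where g(t) = 1 - erd_depth inside the ERD window on the contralateral
channel and g(t) = 1 everywhere else.  Phases phi, psi are drawn once per
trial; the noise is i.i.d. Gaussian per channel and sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import h5py
import numpy as np
from scipy import signal as _sig

__all__ = [
    "SynthConfig",
    "LabeledTrial",
    "TrialSet",
    "synthesize_trial",
    "synthesize_dataset",
    "band_power",
    "save_trialset",
    "load_trialset",
    "CHANNEL_NAMES",
    "LABELS",
]

CHANNEL_NAMES = ("C3", "Cz", "C4")
#: label -> integer code used in HDF5 archives
LABELS = {"left": 0, "right": 1}
#: label -> index of the attenuated (contralateral) channel
_CONTRA = {"left": 2, "right": 0}  # left hand -> C4, right hand -> C3


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults are the strong-effect fixture."""

    sampling_rate: float = 250.0  # Hz
    n_channels: int = 3  # fixed: C3, Cz, C4
    trial_duration: float = 8.0  # s
    cue_time: float = 3.0  # s from trial start
    mu_freq: float = 10.0  # Hz
    beta_freq: float = 22.0  # Hz
    mu_amp: float = 1.0
    beta_amp: float = 1.0
    noise_sd: float = 0.5
    erd_depth: float = 0.8  # attenuation fraction d in [0, 1]
    erd_window: tuple[float, float] = (0.3, 2.8)  # s relative to cue
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.erd_depth <= 1.0):
            raise ValueError(f"erd_depth must be in [0, 1], got {self.erd_depth}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.n_channels != 3:
            raise ValueError("exactly 3 channels (C3, Cz, C4) are supported")
        if not self.erd_window[0] < self.erd_window[1]:
            raise ValueError("erd_window start must precede end")
        if self.cue_time + self.erd_window[1] > self.trial_duration:
            raise ValueError("ERD window extends beyond the trial")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration * self.sampling_rate))

    @property
    def cue_index(self) -> int:
        return int(round(self.cue_time * self.sampling_rate))


@dataclass
class LabeledTrial:
    """One raw multi-channel trial with its class label and cue position."""

    data: np.ndarray  # (3, n_samples)
    label: str  # "left" | "right"
    cue_index: int
    sampling_rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != 3:
            raise ValueError("trial data must have shape (3, n_samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trial data must be finite")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {sorted(LABELS)}, got {self.label!r}")
        if not 0 <= self.cue_index < self.data.shape[1]:
            raise ValueError("cue_index out of range")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class TrialSet:
    """Ordered collection of trials sharing sampling rate and channels."""

    trials: list[LabeledTrial]
    metadata: SynthConfig | dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rates = {t.sampling_rate for t in self.trials}
        if len(rates) > 1:
            raise ValueError("all trials must share one sampling rate")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[LabeledTrial]:
        return iter(self.trials)

    def __getitem__(self, i: int) -> LabeledTrial:
        return self.trials[i]

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.trials]


def synthesize_trial(
    cfg: SynthConfig, label: str, rng: np.random.Generator
) -> LabeledTrial:
    """Generate one trial under the ERD signal model.

    The contralateral channel (C4 for left-hand, C3 for right-hand imagery)
    has both oscillations scaled by ``1 - erd_depth`` inside the ERD window;
    Cz and the ipsilateral channel are never attenuated.
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {sorted(LABELS)}, got {label!r}")
    n = cfg.n_samples
    t = np.arange(n) / cfg.sampling_rate
    phi, psi = rng.uniform(0.0, 2.0 * np.pi, size=2)
    mu = cfg.mu_amp * np.sin(2 * np.pi * cfg.mu_freq * t + phi)
    beta = cfg.beta_amp * np.sin(2 * np.pi * cfg.beta_freq * t + psi)
    osc = mu + beta

    gain = np.ones((3, n))
    lo = cfg.cue_time + cfg.erd_window[0]
    hi = cfg.cue_time + cfg.erd_window[1]
    in_window = (t >= lo) & (t < hi)
    gain[_CONTRA[label], in_window] = 1.0 - cfg.erd_depth

    noise = rng.normal(0.0, cfg.noise_sd, size=(3, n)) if cfg.noise_sd > 0 else 0.0
    data = noise + gain * osc[None, :]
    return LabeledTrial(
        data=data,
        label=label,
        cue_index=cfg.cue_index,
        sampling_rate=cfg.sampling_rate,
    )


def synthesize_dataset(
    cfg: SynthConfig, n_per_class: int, seed: int | None = None
) -> TrialSet:
    """Generate a balanced set of ``2 * n_per_class`` trials.

    Trials alternate left/right and each trial draws from its own
    deterministic sub-stream spawned from ``seed`` (default ``cfg.seed``),
    so any prefix of the set is reproducible independently of length.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    seed = cfg.seed if seed is None else seed
    streams = np.random.SeedSequence(seed).spawn(2 * n_per_class)
    trials = []
    for i, ss in enumerate(streams):
        label = "left" if i % 2 == 0 else "right"
        trials.append(synthesize_trial(cfg, label, np.random.default_rng(ss)))
    return TrialSet(trials=trials, metadata=cfg)


def band_power(
    trial: LabeledTrial,
    channel: int,
    band: tuple[float, float],
    window: tuple[float, float],
) -> float:
    """Periodogram power of one channel integrated over a frequency band.

    Power is on the mean-square scale (``scaling='spectrum'``), so a
    unit-amplitude in-band sinusoid yields ~0.5.  Used as an independent
    oracle for the ERD effect size.
    """
    fs = trial.sampling_rate
    if not (0.0 < band[0] < band[1] < fs / 2):
        raise ValueError("band must satisfy 0 < low < high < Nyquist")
    i0 = int(round(window[0] * fs))
    i1 = int(round(window[1] * fs))
    if not (0 <= i0 < i1 <= trial.n_samples):
        raise ValueError("window out of trial bounds or empty")
    seg = trial.data[channel, i0:i1]
    freqs, pxx = _sig.periodogram(seg, fs=fs, scaling="spectrum")
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(pxx[sel].sum())


def save_trialset(trials: TrialSet, path: str) -> None:
    """Write a TrialSet to HDF5 (/data, /labels, /cue_index + attrs)."""
    data = np.stack([t.data for t in trials])
    labels = np.array([LABELS[t.label] for t in trials], dtype=np.int64)
    cues = np.array([t.cue_index for t in trials], dtype=np.int64)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=data)
        f.create_dataset("labels", data=labels)
        f.create_dataset("cue_index", data=cues)
        f.attrs["sampling_rate"] = trials.trials[0].sampling_rate
        f.attrs["channel_names"] = list(CHANNEL_NAMES)


def load_trialset(path: str) -> TrialSet:
    """Read a TrialSet from the HDF5 layout written by :func:`save_trialset`."""
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        labels = f["labels"][()]
        cues = f["cue_index"][()]
        fs = float(f.attrs["sampling_rate"])
        names = [
            n.decode() if isinstance(n, bytes) else str(n)
            for n in f.attrs["channel_names"]
        ]
    if tuple(names) != CHANNEL_NAMES:
        raise ValueError(f"channel order must be {CHANNEL_NAMES}, got {tuple(names)}")
    code_to_label = {v: k for k, v in LABELS.items()}
    trials = [
        LabeledTrial(data=d, label=code_to_label[int(l)], cue_index=int(c), sampling_rate=fs)
        for d, l, c in zip(data, labels, cues)
    ]
    return TrialSet(trials=trials, metadata={"source": path})
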