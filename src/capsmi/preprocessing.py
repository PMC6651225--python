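"""Band-pass filtering and cue-locked epoch extraction.

Raw trials are filtered 4-38 Hz (covering the mu and beta bands) with a
zero-phase 4th-order Butterworth, then the 0.5-2.5 s post-cue segment is
cut out: at 250 Hz that is exactly 500 samples per channel.  Filtering is
applied to the full trial *before* epoching so filter edge transients fall
outside the analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from scipy import signal as _sig

from .synth import CHANNEL_NAMES, LABELS, LabeledTrial, TrialSet

__all__ = [
    "FilterSpec",
    "EpochSet",
    "bandpass_filter",
    "extract_epoch",
    "build_epochset",
    "save_epochset",
    "load_epochset",
    "read_gdf_trials",
]

EPOCH_WINDOW = (0.5, 2.5)  # s after cue


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth band-pass settings."""

    low_cut: float = 4.0  # Hz
    high_cut: float = 38.0  # Hz
    order: int = 4
    zero_phase: bool = True

    def validate(self, sampling_rate: float) -> None:
        if not (0.0 < self.low_cut < self.high_cut < sampling_rate / 2):
            raise ValueError(
                f"cutoffs must satisfy 0 < {self.low_cut} < {self.high_cut} "
                f"< Nyquist ({sampling_rate / 2})"
            )


@dataclass
class EpochSet:
    """Stack of filtered cue-locked epochs: (n_trials, 3, n_epoch_samples)."""

    data: np.ndarray
    labels: np.ndarray  # integer codes, 0=left 1=right
    sampling_rate: float = 250.0
    window: tuple[float, float] = EPOCH_WINDOW

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3 or self.data.shape[1] != 3:
            raise ValueError("epoch data must have shape (n_trials, 3, n_samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal number of trials")

    def __len__(self) -> int:
        return self.data.shape[0]


def bandpass_filter(
    signal: np.ndarray, sampling_rate: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Band-pass each channel; zero-phase mode introduces no group delay."""
    spec.validate(sampling_rate)
    signal = np.asarray(signal, dtype=np.float64)
    sos = _sig.butter(
        spec.order,
        [spec.low_cut, spec.high_cut],
        btype="bandpass",
        fs=sampling_rate,
        output="sos",
    )
    if signal.shape[-1] <= 3 * (2 * spec.order + 1):
        raise ValueError("signal too short for stable zero-phase filtering")
    if spec.zero_phase:
        return _sig.sosfiltfilt(sos, signal, axis=-1)
    return _sig.sosfilt(sos, signal, axis=-1)


def epoch_slice(
    cue_index: int, sampling_rate: float, window: tuple[float, float] = EPOCH_WINDOW
) -> slice:
    """Half-open sample range of the analysis window (0-based, round(t*fs))."""
    start = cue_index + int(round(window[0] * sampling_rate))
    stop = cue_index + int(round(window[1] * sampling_rate))
    return slice(start, stop)


def extract_epoch(
    trial: LabeledTrial, window: tuple[float, float] = EPOCH_WINDOW
) -> np.ndarray:
    """Cut the post-cue analysis segment out of a (possibly filtered) trial.

    With the default window and 250 Hz sampling the epoch is 3 x 500.
    """
    if not window[0] < window[1]:
        raise ValueError(f"degenerate epoch window {window}")
    sl = epoch_slice(trial.cue_index, trial.sampling_rate, window)
    if sl.start < 0 or sl.stop > trial.n_samples:
        raise ValueError(
            f"epoch window {window} exceeds trial bounds "
            f"(cue {trial.cue_index}, {trial.n_samples} samples)"
        )
    return trial.data[:, sl]


def build_epochset(
    trials: TrialSet,
    spec: FilterSpec = FilterSpec(),
    window: tuple[float, float] = EPOCH_WINDOW,
) -> EpochSet:
    """Filter each full trial, then epoch; labels carried through in order."""
    epochs, labels = [], []
    fs = None
    for i, trial in enumerate(trials):
        fs = trial.sampling_rate
        try:
            filtered = bandpass_filter(trial.data, fs, spec)
            filtered_trial = LabeledTrial(
                data=filtered,
                label=trial.label,
                cue_index=trial.cue_index,
                sampling_rate=fs,
            )
            epochs.append(extract_epoch(filtered_trial, window))
        except ValueError as exc:
            raise ValueError(f"trial {i}: {exc}") from exc
        labels.append(LABELS[trial.label])
    if not epochs:
        raise ValueError("empty trial set")
    return EpochSet(
        data=np.stack(epochs), labels=np.array(labels), sampling_rate=fs, window=window
    )


def save_epochset(epochs: EpochSet, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epochs.data)
        f.create_dataset("labels", data=epochs.labels)
        f.attrs["fs"] = epochs.sampling_rate
        f.attrs["window"] = list(epochs.window)


def load_epochset(path: str) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["epochs"][()],
            labels=f["labels"][()],
            sampling_rate=float(f.attrs["fs"]),
            window=tuple(f.attrs["window"]),
        )


def read_gdf_trials(
    path: str,
    left_code: str = "769",
    right_code: str = "770",
    channels: tuple[str, ...] = CHANNEL_NAMES,
) -> TrialSet:
    """Read cue-annotated trials from a GDF recording (BCI IV 2b layout).

    Requires :mod:`mne` (optional dependency, extra ``gdf``).  Cue
    annotations 769/770 mark left/right-hand imagery onsets; each trial is
    the recording from cue minus 3 s to cue plus 5 s so the default
    generator geometry (cue at 3 s in an 8 s trial) is preserved.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading GDF files requires mne (pip install capsmi[gdf])") from exc

    raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    picks = [
        i for i, name in enumerate(raw.ch_names)
        if any(c.lower() in name.lower() for c in channels)
    ]
    if len(picks) != 3:
        raise ValueError(f"expected 3 EEG channels {channels}, found {len(picks)}")
    data = raw.get_data(picks=picks)
    code_to_label = {left_code: "left", right_code: "right"}
    pre, post = int(round(3.0 * fs)), int(round(5.0 * fs))
    trials = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if desc not in code_to_label:
            continue
        cue = int(round(onset * fs))
        if cue - pre < 0 or cue + post > data.shape[1]:
            continue
        trials.append(
            LabeledTrial(
                data=data[:, cue - pre : cue + post],
                label=code_to_label[desc],
                cue_index=pre,
                sampling_rate=fs,
            )
        )
    return TrialSet(trials=trials, metadata={"source": path})
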