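"""Feature extraction for multi-channel EEG trials.

Raw trials (channels x samples, with a pre-stimulus baseline segment and
valence/arousal ratings on a 1-9 scale) are turned into the two aligned
model inputs:

* a differential-entropy (DE) tensor, one value per non-overlapping
  window, channel and frequency band, baseline-corrected and standardized;
* a time-domain tensor of baseline-median-corrected, standardized window
  waveforms (optionally block-averaged down to a coarser time axis for
  the recurrent branch).

Standardization statistics are always estimated on training windows only
and then applied unchanged to validation/test windows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

log = logging.getLogger(__name__)

__all__ = [
    "EEGTrial",
    "Band",
    "DEFAULT_BANDS",
    "FeaturePair",
    "ScalerStats",
    "CLASS_NAMES",
    "segment_windows",
    "baseline_correct_time",
    "compute_de",
    "baseline_correct_de",
    "derive_label",
    "extract_features",
    "fit_scaler",
    "apply_scaler",
]

#: 4-quadrant class index order used everywhere in the package.
CLASS_NAMES = ("HVHA", "LVHA", "LVLA", "HVLA")

#: Variance floor applied before the log in the DE formula so that a
#: constant (zero-variance) window yields a finite value.
VARIANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class Band:
    name: str
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"band {self.name}: low must be < high")


#: The five canonical EEG rhythm bands (Hz).
DEFAULT_BANDS: tuple[Band, ...] = (
    Band("delta", 1.0, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 14.0),
    Band("beta", 14.0, 30.0),
    Band("gamma", 30.0, 45.0),
)


@dataclass
class EEGTrial:
    """One stimulus presentation: signal, pre-stimulus baseline, ratings."""

    subject_id: str
    trial_id: str
    signal: np.ndarray  # [n_channels, n_samples], microvolts
    baseline: np.ndarray  # [n_channels, n_baseline_samples], microvolts
    fs: float  # Hz
    channel_names: list[str]
    valence: float  # 1..9
    arousal: float  # 1..9

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.baseline = np.asarray(self.baseline, dtype=np.float64)
        if self.signal.ndim != 2 or self.baseline.ndim != 2:
            raise ValueError(f"trial {self.trial_id}: signal/baseline must be 2-D")
        if self.signal.shape[0] != len(self.channel_names):
            raise ValueError(
                f"trial {self.trial_id}: {self.signal.shape[0]} signal rows but "
                f"{len(self.channel_names)} channel names"
            )
        if self.baseline.shape[0] != self.signal.shape[0]:
            raise ValueError(f"trial {self.trial_id}: baseline channel count mismatch")
        if not self.fs > 0:
            raise ValueError(f"trial {self.trial_id}: fs must be positive")
        for name, r in (("valence", self.valence), ("arousal", self.arousal)):
            if not (1.0 <= r <= 9.0):
                raise ValueError(f"trial {self.trial_id}: {name}={r} outside [1, 9]")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]


@dataclass
class FeaturePair:
    """Aligned frequency-domain and time-domain inputs plus labels.

    de:   [n_windows, n_channels, n_bands]  (nats)
    time: [n_windows, n_channels, n_time_steps]
    labels: [n_windows] integers indexing CLASS_NAMES
    """

    de: np.ndarray
    time: np.ndarray
    labels: np.ndarray
    window_s: float = 3.0
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.de.shape[0] != self.time.shape[0] or self.de.shape[0] != len(self.labels):
            raise ValueError("de/time/labels disagree on window count")
        if self.de.shape[1] != self.time.shape[1]:
            raise ValueError("de/time disagree on channel count")

    @property
    def n_windows(self) -> int:
        return self.de.shape[0]

    @property
    def n_channels(self) -> int:
        return self.de.shape[1]

    def subset(self, idx) -> "FeaturePair":
        return FeaturePair(
            de=self.de[idx],
            time=self.time[idx],
            labels=self.labels[idx],
            window_s=self.window_s,
            channel_names=list(self.channel_names),
        )

    def restrict_channels(self, keep: np.ndarray) -> "FeaturePair":
        """Keep only the given channel indices (for electrode-reduction runs)."""
        keep = np.asarray(keep)
        return FeaturePair(
            de=self.de[:, keep, :],
            time=self.time[:, keep, :],
            labels=self.labels,
            window_s=self.window_s,
            channel_names=[self.channel_names[i] for i in keep]
            if self.channel_names
            else [],
        )


# --------------------------------------------------------------- windowing
def segment_windows(trial: EEGTrial, window_s: float = 3.0) -> list[np.ndarray]:
    """Cut the stimulus signal into contiguous non-overlapping windows.

    Returns floor(n_samples / (window_s * fs)) matrices of identical shape,
    in temporal order; a trailing partial window is dropped.  The baseline
    segment is never part of the output.
    """
    w = int(round(window_s * trial.fs))
    if w < 1:
        raise ValueError("window shorter than one sample")
    n = trial.signal.shape[1]
    if n < w:
        raise ValueError(
            f"trial {trial.trial_id}: signal of {n} samples is shorter than one "
            f"{window_s}-s window ({w} samples)"
        )
    k = n // w
    return [trial.signal[:, i * w : (i + 1) * w] for i in range(k)]


def baseline_correct_time(window: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Subtract each channel's baseline median from the window samples."""
    window = np.asarray(window, dtype=np.float64)
    baseline = np.asarray(baseline, dtype=np.float64)
    if baseline.size == 0:
        raise ValueError("empty baseline")
    if window.shape[0] != baseline.shape[0]:
        raise ValueError("window/baseline channel mismatch")
    return window - np.median(baseline, axis=1, keepdims=True)


# ------------------------------------------------------------------------ DE
def _bandpass_sos(low: float, high: float, fs: float):
    return sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def compute_de(
    x: np.ndarray,
    band: Band | tuple[float, float],
    fs: float,
    skip_filter: bool = False,
) -> float:
    """Differential entropy of one channel-window in one frequency band.

    The signal is band-passed with a 4th-order zero-phase Butterworth
    filter, then DE = 0.5 * ln(2*pi*e*var) under the Gaussian assumption.
    ``skip_filter=True`` bypasses the filter and returns the Gaussian DE of
    the raw samples (closed-form testing path).
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if not skip_filter:
        if isinstance(band, Band):
            low, high = band.low, band.high
        else:
            low, high = band
        if fs <= 2 * high:
            raise ValueError(f"fs={fs} violates Nyquist for band ({low}, {high})")
        x = sps.sosfiltfilt(_bandpass_sos(low, high, fs), x)
    var = float(np.var(x))
    if var < VARIANCE_FLOOR:
        warnings.warn("zero-variance window in DE; variance floored", RuntimeWarning)
        var = VARIANCE_FLOOR
    return 0.5 * np.log(2.0 * np.pi * np.e * var)


def _de_matrix(windows: np.ndarray, bands, fs: float, skip_filter: bool) -> np.ndarray:
    """DE for a stack of windows: [n_win, n_ch, n_samp] -> [n_win, n_ch, n_bands].

    Vectorized: each band filter runs once over the whole stack.
    """
    windows = np.asarray(windows, dtype=np.float64)
    n_win, n_ch, _ = windows.shape
    out = np.empty((n_win, n_ch, len(bands)))
    for b, band in enumerate(bands):
        if skip_filter:
            filt = windows
        else:
            if fs <= 2 * band.high:
                raise ValueError(f"fs={fs} violates Nyquist for band {band.name}")
            filt = sps.sosfiltfilt(_bandpass_sos(band.low, band.high, fs), windows, axis=-1)
        var = np.maximum(filt.var(axis=-1), VARIANCE_FLOOR)
        out[:, :, b] = 0.5 * np.log(2.0 * np.pi * np.e * var)
    return out


def baseline_correct_de(de_windows: np.ndarray, de_baseline: np.ndarray) -> np.ndarray:
    """Subtract the mean baseline DE (over baseline windows) per channel-band."""
    de_windows = np.asarray(de_windows)
    de_baseline = np.asarray(de_baseline)
    if de_baseline.size == 0:
        raise ValueError("missing baseline DE")
    if de_baseline.ndim == 2:  # single baseline window
        de_baseline = de_baseline[None]
    if de_baseline.shape[1:] != de_windows.shape[1:]:
        raise ValueError("baseline DE channel/band mismatch")
    return de_windows - de_baseline.mean(axis=0)


# ---------------------------------------------------------------- labeling
def derive_label(valence: float, arousal: float) -> int:
    """Quadrant class from thresholding both axes at 5 (5 itself is High)."""
    for name, r in (("valence", valence), ("arousal", arousal)):
        if not (1.0 <= r <= 9.0):
            raise ValueError(f"{name}={r} outside [1, 9]")
    hv = valence >= 5.0
    ha = arousal >= 5.0
    if hv and ha:
        return CLASS_NAMES.index("HVHA")
    if not hv and ha:
        return CLASS_NAMES.index("LVHA")
    if not hv and not ha:
        return CLASS_NAMES.index("LVLA")
    return CLASS_NAMES.index("HVLA")


# --------------------------------------------------------------- extraction
def _downsample_time(windows: np.ndarray, factor: int) -> np.ndarray:
    """Non-overlapping block means along the sample axis (trailing remainder dropped)."""
    if factor <= 1:
        return windows
    n = windows.shape[-1] // factor
    trimmed = windows[..., : n * factor]
    return trimmed.reshape(*windows.shape[:-1], n, factor).mean(axis=-1)


def extract_features(
    trials,
    window_s: float = 3.0,
    bands=DEFAULT_BANDS,
    skip_filter: bool = False,
    time_downsample: int = 1,
) -> FeaturePair:
    """Full per-trial feature pipeline over a list of trials.

    Per trial: segment into windows; subtract the baseline median from the
    time-domain samples; compute per-band DE for each window and for the
    baseline (segmented at the same window length, or taken whole if it is
    shorter than one window) and subtract the mean baseline DE.  Windows of
    all trials are concatenated, each labeled with its trial's quadrant.

    ``time_downsample`` block-averages the time-domain windows by an
    integer factor; it only changes the recurrent branch's time resolution,
    never the DE computation.
    """
    if isinstance(trials, EEGTrial):
        trials = [trials]
    if not trials:
        raise ValueError("no trials")
    de_all, time_all, labels = [], [], []
    names = list(trials[0].channel_names)
    for trial in trials:
        if list(trial.channel_names) != names:
            raise ValueError("trials disagree on channel names/order")
        wins = np.stack(segment_windows(trial, window_s))  # [W, C, S]
        corrected = wins - np.median(trial.baseline, axis=1)[None, :, None]
        de_w = _de_matrix(wins, bands, trial.fs, skip_filter)
        # baseline DE windows: same window length; a baseline shorter than
        # one window is used whole
        w = int(round(window_s * trial.fs))
        nb = trial.baseline.shape[1] // w
        if nb >= 1:
            bl_wins = np.stack(
                [trial.baseline[:, i * w : (i + 1) * w] for i in range(nb)]
            )
        else:
            bl_wins = trial.baseline[None]
        de_b = _de_matrix(bl_wins, bands, trial.fs, skip_filter)
        de_all.append(baseline_correct_de(de_w, de_b))
        time_all.append(_downsample_time(corrected, time_downsample))
        labels.extend([derive_label(trial.valence, trial.arousal)] * wins.shape[0])
    return FeaturePair(
        de=np.concatenate(de_all),
        time=np.concatenate(time_all),
        labels=np.asarray(labels, dtype=np.intp),
        window_s=window_s,
        channel_names=names,
    )


# ------------------------------------------------------------------ scaling
@dataclass
class ScalerStats:
    """Standardization statistics fit on training windows only.

    Time domain: one (mean, std) per channel, pooled over windows and
    samples.  DE domain: one (mean, std) per channel-band cell.
    """

    time_mean: np.ndarray  # [n_channels]
    time_std: np.ndarray  # [n_channels]
    de_mean: np.ndarray  # [n_channels, n_bands]
    de_std: np.ndarray  # [n_channels, n_bands]


_STD_FLOOR = 1e-8


def fit_scaler(train: FeaturePair) -> ScalerStats:
    if train.n_windows == 0:
        raise ValueError("empty training set")
    t_mean = train.time.mean(axis=(0, 2))
    t_std = train.time.std(axis=(0, 2))
    d_mean = train.de.mean(axis=0)
    d_std = train.de.std(axis=0)
    if np.any(t_std < _STD_FLOOR) or np.any(d_std < _STD_FLOOR):
        warnings.warn("constant feature: std floored", RuntimeWarning)
    return ScalerStats(
        time_mean=t_mean,
        time_std=np.maximum(t_std, _STD_FLOOR),
        de_mean=d_mean,
        de_std=np.maximum(d_std, _STD_FLOOR),
    )


def apply_scaler(features: FeaturePair, stats: ScalerStats) -> FeaturePair:
    time = (features.time - stats.time_mean[None, :, None]) / stats.time_std[None, :, None]
    de = (features.de - stats.de_mean[None]) / stats.de_std[None]
    return FeaturePair(
        de=de,
        time=time,
        labels=features.labels,
        window_s=features.window_s,
        channel_names=list(features.channel_names),
    )
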