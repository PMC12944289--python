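"""Synthetic EEG subjects with known class structure.

Each simulated trial is a sum of band-limited oscillations (one carrier
per canonical rhythm band and channel, with the carrier frequency and
phase redrawn uniformly inside the band for every 3-s block, so analysis
windows are internally stationary but mutually independent) plus 1/f
(pink) and white background noise, with a
pre-stimulus baseline segment generated without any class effect, and
valence/arousal ratings drawn consistently with the trial's quadrant.

Two complementary, independently switchable class cues are injected on a
known set of "informative" electrodes, so that ground truth is available
for every pipeline stage:

* **spectral cue** (frequency branch): the class determines *which* band
  carries extra amplitude (by default alpha for high-valence classes,
  beta for low-valence ones, with equal base amplitudes, so total
  per-channel variance is class-independent and the cue is visible in
  band-wise differential entropy but nearly invisible in the raw
  waveform's envelope);
* **temporal cue** (time branch): a smooth low-frequency transient of
  fixed shape and amplitude whose *latency* within each analysis window
  depends on the arousal class (an LPP-like deflection) — invisible to
  variance-based band features, easy for a recurrent model.

With both cues active, neither branch alone can separate all four
quadrants, which is exactly the regime where branch fusion must help.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import CLASS_NAMES, EEGTrial
from .graph import DEAP32_CHANNELS

__all__ = ["SimConfig", "SimDataset", "GroundTruth", "simulate_subject", "ground_truth"]

#: Base oscillation amplitude per band.  alpha and beta are deliberately
#: equal so the default spectral cue does not change total signal power.
BASE_AMPLITUDES = {
    "delta": 1.0,
    "theta": 0.8,
    "alpha": 0.7,
    "beta": 0.7,
    "gamma": 0.5,
}

BAND_EDGES = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 14.0),
    "beta": (14.0, 30.0),
    "gamma": (30.0, 45.0),
}

#: class -> (valence mean, arousal mean) on the 1-9 scale
RATING_MEANS = {
    "HVHA": (7.0, 7.0),
    "LVHA": (3.0, 7.0),
    "LVLA": (3.0, 3.0),
    "HVLA": (7.0, 3.0),
}


def default_class_band_map(multiplier: float = 2.5) -> dict:
    """Valence coded by band identity: alpha boosted for HV, beta for LV."""
    return {
        "HVHA": {"alpha": multiplier},
        "HVLA": {"alpha": multiplier},
        "LVHA": {"beta": multiplier},
        "LVLA": {"beta": multiplier},
    }


@dataclass
class SimConfig:
    channel_names: list[str] = field(default_factory=lambda: list(DEAP32_CHANNELS))
    fs: float = 128.0
    trial_s: float = 60.0
    baseline_s: float = 3.0
    n_trials: int = 40
    informative_channels: tuple = ("F7", "T8", "CP6", "P4", "FC5")
    class_band_map: dict | None = None  # None -> default_class_band_map()
    snr: float = 3.0  # oscillation power / noise power; 0 = noise only
    temporal_cue_amplitude: float = 1.5  # 0 disables the temporal cue
    temporal_cue_period_s: float = 3.0
    # latency of the transient within each cue period: length 2 codes arousal
    # (high, low); length 4 codes the full class in CLASS_NAMES order
    temporal_cue_latencies: tuple = (0.6, 1.8)
    temporal_cue_width_s: float = 0.15
    rating_jitter: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.class_band_map is None:
            self.class_band_map = default_class_band_map()
        missing = [c for c in self.informative_channels if c not in self.channel_names]
        if missing:
            raise ValueError(f"informative channels not in montage: {missing}")
        for cls, bands in self.class_band_map.items():
            if cls not in CLASS_NAMES:
                raise ValueError(f"unknown class {cls!r}")
            for b, m in bands.items():
                if b not in BAND_EDGES:
                    raise ValueError(f"unknown band {b!r}")
                if not m > 0:
                    raise ValueError("band multipliers must be positive")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    informative_channels: tuple
    class_band_map: dict


@dataclass
class SimDataset:
    trials: list
    truth: GroundTruth
    config: SimConfig


def _pink_noise_block(rng: np.random.Generator, n_ch: int, n_samp: int,
                      fs: float) -> np.ndarray:
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])
    shaping[0] = 0.0
    pink = np.fft.irfft(spec * shaping, n=n_samp, axis=-1)
    sd = pink.std(axis=-1, keepdims=True)
    return pink / np.maximum(sd, 1e-12)


def _pink_noise(rng: np.random.Generator, n_ch: int, n_samp: int, fs: float,
                block_s: float = 3.0) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise per channel (FFT shaping).

    Generated independently per non-overlapping block, like the oscillation
    carriers: 1/f noise synthesized over a whole trial carries long-range
    correlations that make windows of one trial mutually predictive, which
    would leak trial identity across a window-level split.
    """
    blk = max(8, int(round(block_s * fs)))
    out = np.empty((n_ch, n_samp))
    for s in range(0, n_samp, blk):
        e = min(s + blk, n_samp)
        out[:, s:e] = _pink_noise_block(rng, n_ch, e - s, fs)
    return out


def _oscillations(
    rng: np.random.Generator,
    n_ch: int,
    n_samp: int,
    fs: float,
    amp: np.ndarray,  # [n_ch, n_bands]
    block_s: float = 3.0,
) -> np.ndarray:
    """Band-limited oscillations; carriers redrawn per non-overlapping block.

    Per-block redrawing keeps each analysis window stationary while making
    windows of the same trial independent of each other, so a window-level
    split cannot recover trial identity from the spectrum alone.
    """
    out = np.zeros((n_ch, n_samp))
    blk = max(1, int(round(block_s * fs)))
    for s in range(0, n_samp, blk):
        e = min(s + blk, n_samp)
        t = np.arange(s, e) / fs
        for b, (low, high) in enumerate(BAND_EDGES.values()):
            f = rng.uniform(low, high, size=n_ch)
            phi = rng.uniform(0, 2 * np.pi, size=n_ch)
            out[:, s:e] += amp[:, b, None] * np.sin(
                2 * np.pi * f[:, None] * t[None] + phi[:, None]
            )
    return out


def _amplitude_matrix(cfg: SimConfig, class_name: str | None) -> np.ndarray:
    """Per-channel, per-band oscillation amplitudes (class effect applied
    on informative channels only; ``class_name=None`` means no effect)."""
    base = np.array(list(BASE_AMPLITUDES.values()))
    amp = np.tile(base, (len(cfg.channel_names), 1))
    if class_name is not None:
        mults = cfg.class_band_map.get(class_name, {})
        band_names = list(BAND_EDGES)
        info_idx = [cfg.channel_names.index(c) for c in cfg.informative_channels]
        for band, m in mults.items():
            amp[info_idx, band_names.index(band)] *= m
    return amp


def _transient(cfg: SimConfig, n_samp: int, class_name: str, power0: float) -> np.ndarray:
    """Class-latency bump train added to the informative channels."""
    t = np.arange(n_samp) / cfg.fs
    lats = cfg.temporal_cue_latencies
    if len(lats) == 4:
        latency = lats[CLASS_NAMES.index(class_name)]
    elif len(lats) == 2:
        latency = lats[0 if class_name in ("HVHA", "LVHA") else 1]
    else:
        raise ValueError("temporal_cue_latencies must have length 2 or 4")
    phase = np.mod(t - latency, cfg.temporal_cue_period_s)
    # distance to nearest bump center, wrapped
    d = np.minimum(phase, cfg.temporal_cue_period_s - phase)
    bump = np.exp(-0.5 * (d / cfg.temporal_cue_width_s) ** 2)
    return cfg.temporal_cue_amplitude * np.sqrt(power0) * bump


def _draw_rating(rng: np.random.Generator, mean: float, jitter: float) -> float:
    """Rating near `mean`, clipped to stay on its side of the 5 threshold."""
    r = mean + jitter * rng.standard_normal()
    if mean >= 5.0:
        return float(np.clip(r, 5.0, 9.0))
    return float(np.clip(r, 1.0, 4.99))


def simulate_subject(config: SimConfig, subject_id: str = "sim00") -> SimDataset:
    """Generate one synthetic subject; fully determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_ch = len(config.channel_names)
    n_samp = int(round(config.trial_s * config.fs))
    n_base = int(round(config.baseline_s * config.fs))
    power0 = sum(a**2 / 2 for a in BASE_AMPLITUDES.values())  # nominal osc power
    # balanced class assignment, then shuffled
    classes = [CLASS_NAMES[i % 4] for i in range(config.n_trials)]
    rng.shuffle(classes)
    trials = []
    for k, cls in enumerate(classes):
        if config.snr > 0:
            blk = config.temporal_cue_period_s
            sig = _oscillations(rng, n_ch, n_samp, config.fs,
                                _amplitude_matrix(config, cls), block_s=blk)
            base = _oscillations(rng, n_ch, n_base, config.fs,
                                 _amplitude_matrix(config, None), block_s=blk)
            noise_sd = np.sqrt(power0 / config.snr)
        else:  # pure-noise subject: no class-dependent signal at all
            sig = np.zeros((n_ch, n_samp))
            base = np.zeros((n_ch, n_base))
            noise_sd = np.sqrt(power0)
        if config.temporal_cue_amplitude > 0 and config.snr > 0:
            info_idx = [config.channel_names.index(c)
                        for c in config.informative_channels]
            sig[info_idx] += _transient(config, n_samp, cls, power0)[None]
        for seg, n in ((sig, n_samp), (base, n_base)):
            seg += noise_sd * (
                0.8 * _pink_noise(rng, n_ch, n, config.fs)
                + 0.6 * rng.standard_normal((n_ch, n))
            )
        v_mean, a_mean = RATING_MEANS[cls]
        trials.append(
            EEGTrial(
                subject_id=subject_id,
                trial_id=f"trial{k:03d}",
                signal=sig,
                baseline=base,
                fs=config.fs,
                channel_names=list(config.channel_names),
                valence=_draw_rating(rng, v_mean, config.rating_jitter),
                arousal=_draw_rating(rng, a_mean, config.rating_jitter),
            )
        )
    truth = GroundTruth(
        informative_channels=tuple(config.informative_channels),
        class_band_map={c: dict(b) for c, b in config.class_band_map.items()},
    )
    return SimDataset(trials=trials, truth=truth, config=config)


def ground_truth(dataset: SimDataset) -> GroundTruth:
    """The generating configuration, for recovery tests."""
    return dataset.truth
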