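"""Dataset container readers/writers and run configuration.

Container schema (HDF5, one file per subject; an ``.npz`` fallback with
the same keys is accepted):

    /trial_000/signal     float [n_channels, n_samples]   (microvolts)
    /trial_000/baseline   float [n_channels, n_baseline_samples]
    /trial_000@fs         sampling rate, Hz
    /trial_000@valence    rating in [1, 9]
    /trial_000@arousal    rating in [1, 9]
    /@channel_names       ordered channel labels (file-level)
    /@subject_id          opaque string

A small adapter reads DEAP-style preprocessed per-subject pickles
(40 trials x 40 channels x 8064 samples at 128 Hz; the first 32 channels
are EEG and the first 384 samples are the 3-s pre-stimulus baseline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .features import EEGTrial

log = logging.getLogger(__name__)

__all__ = ["save_subject", "load_subject", "load_deap_subject", "RunConfig"]


def save_subject(trials: list, path) -> None:
    """Write trials of one subject to the HDF5 container."""
    if not trials:
        raise ValueError("no trials to save")
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["subject_id"] = trials[0].subject_id
        f.attrs["channel_names"] = [str(c) for c in trials[0].channel_names]
        for k, tr in enumerate(trials):
            g = f.create_group(f"trial_{k:03d}")
            g.create_dataset("signal", data=tr.signal)
            g.create_dataset("baseline", data=tr.baseline)
            g.attrs["fs"] = tr.fs
            g.attrs["valence"] = tr.valence
            g.attrs["arousal"] = tr.arousal
            g.attrs["trial_id"] = tr.trial_id


def load_subject(path) -> list:
    """Read a subject container (HDF5 or NPZ) into validated trials."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npz":
        return _load_subject_npz(path)
    trials = []
    with h5py.File(path, "r") as f:
        if "channel_names" not in f.attrs:
            raise ValueError(f"{path}: missing file attribute 'channel_names'")
        names = [str(c) for c in f.attrs["channel_names"]]
        subject = str(f.attrs.get("subject_id", path.stem))
        for key in sorted(f.keys()):
            g = f[key]
            for req in ("signal", "baseline"):
                if req not in g:
                    raise ValueError(f"{path}:/{key}: missing dataset '{req}'")
            for req in ("fs", "valence", "arousal"):
                if req not in g.attrs:
                    raise ValueError(f"{path}:/{key}: missing attribute '{req}'")
            trials.append(
                EEGTrial(
                    subject_id=subject,
                    trial_id=str(g.attrs.get("trial_id", key)),
                    signal=g["signal"][()],
                    baseline=g["baseline"][()],
                    fs=float(g.attrs["fs"]),
                    channel_names=list(names),
                    valence=float(g.attrs["valence"]),
                    arousal=float(g.attrs["arousal"]),
                )
            )
    return trials


def _load_subject_npz(path) -> list:
    z = np.load(path, allow_pickle=False)
    if "channel_names" not in z:
        raise ValueError(f"{path}: missing key 'channel_names'")
    names = [str(c) for c in z["channel_names"]]
    subject = str(z["subject_id"]) if "subject_id" in z else path.stem
    ks = sorted({k.split("/")[0] for k in z.files if k.startswith("trial_")})
    trials = []
    for key in ks:
        for req in ("signal", "baseline", "fs", "valence", "arousal"):
            if f"{key}/{req}" not in z:
                raise ValueError(f"{path}: missing key '{key}/{req}'")
        trials.append(
            EEGTrial(
                subject_id=subject,
                trial_id=key,
                signal=z[f"{key}/signal"],
                baseline=z[f"{key}/baseline"],
                fs=float(z[f"{key}/fs"]),
                channel_names=list(names),
                valence=float(z[f"{key}/valence"]),
                arousal=float(z[f"{key}/arousal"]),
            )
        )
    return trials


def load_deap_subject(path, baseline_s: float = 3.0, fs: float = 128.0) -> list:
    """Adapter for DEAP's preprocessed per-subject pickle containers.

    Expects the usual dict with ``data`` [40, 40, 8064] (first 32 rows EEG)
    and ``labels`` [40, 4] (valence, arousal, dominance, liking).  Each 63-s
    trial is split into the 3-s pre-stimulus baseline and the 60-s stimulus
    segment.
    """
    from .graph import DEAP32_CHANNELS

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found. DEAP is a licensed dataset; download the "
            "preprocessed_python containers and point at sNN.dat."
        )
    import pickle

    with open(path, "rb") as fh:
        blob = pickle.load(fh, encoding="latin1")
    if "data" not in blob or "labels" not in blob:
        raise ValueError(f"{path}: not a DEAP preprocessed container")
    data, labels = np.asarray(blob["data"]), np.asarray(blob["labels"])
    nb = int(round(baseline_s * fs))
    trials = []
    for k in range(data.shape[0]):
        eeg = data[k, :32]
        trials.append(
            EEGTrial(
                subject_id=path.stem,
                trial_id=f"trial_{k:03d}",
                signal=eeg[:, nb:],
                baseline=eeg[:, :nb],
                fs=fs,
                channel_names=list(DEAP32_CHANNELS),
                valence=float(labels[k, 0]),
                arousal=float(labels[k, 1]),
            )
        )
    return trials


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (loadable from YAML)."""

    dataset: str | None = None  # None -> simulate
    output_dir: str = "runs"
    # features
    window_s: float = 3.0
    skip_filter: bool = False
    time_downsample: int = 8
    # graph
    montage: str = "deap32"
    tau: float | None = None
    edge_fraction: float = 0.2
    # model: either a fixed variant id (1..4) or "search"
    variant: int | str = 4
    search_epochs: int = 40
    search_seeds: int = 5
    # training
    lr: float = 1e-3
    batch_size: int = 32
    epochs: int = 150
    seed: int = 0
    # simulation (used when dataset is None)
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if cfg.dataset is not None and not Path(cfg.dataset).exists():
            raise FileNotFoundError(cfg.dataset)
        return cfg

    def substream(self, name: str) -> int:
        """Derive a named child seed from the global seed."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(abs(hash(name)) % 2**31,))
        return int(ss.generate_state(1)[0] % 2**31)
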