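"""Shared containers for signals flowing through the pipeline.

All time series run at a common sample rate (default 512 Hz, matching the
EEG acquisition rate the analyses assume). Onset trains are binary impulse
series; envelopes are continuous non-negative amplitude series; model
outputs and EEG recordings carry the pattern-onset markers needed by the
epoching and phase analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SAMPLE_RATE = 512.0

#: Fronto-central electrode cluster over which all EEG analyses average.
CLUSTER_CHANNELS = (
    "Fz", "F3", "F4", "F1", "F2",
    "FCz", "FC3", "FC4", "FC1", "FC2",
    "Cz", "C3", "C4", "C1", "C2",
)


@dataclass
class OnsetSeries:
    """Binary impulse train marking sound (or tap) onsets.

    ``values`` is 1 exactly at ``onset_times`` (sample indices) and 0
    elsewhere. ``pattern_onsets`` marks the start of each repetition of the
    rhythmic pattern; when pattern position 0 is sounded they are a subset
    of ``onset_times``.
    """

    sample_rate: float
    values: np.ndarray
    onset_times: np.ndarray
    pattern_onsets: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.onset_times = np.asarray(self.onset_times, dtype=int)
        self.pattern_onsets = np.asarray(self.pattern_onsets, dtype=int)

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def events_table(self) -> pd.DataFrame:
        """Onset times as an events table (sample, label)."""
        rows = [(int(s), "onset") for s in self.onset_times]
        rows += [(int(s), "pattern_onset") for s in self.pattern_onsets]
        return (
            pd.DataFrame(rows, columns=["sample", "label"])
            .sort_values(["sample", "label"], kind="stable")
            .reset_index(drop=True)
        )


@dataclass
class Envelope:
    """Continuous non-negative stimulus envelope, peak-normalized to 1."""

    sample_rate: float
    values: np.ndarray
    normalization: str = "peak"
    pattern_onsets: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("envelope values must be non-negative")
        if self.pattern_onsets is not None:
            self.pattern_onsets = np.asarray(self.pattern_onsets, dtype=int)

    @property
    def n_samples(self) -> int:
        return self.values.size

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.n_samples) / self.sample_rate
        return pd.DataFrame({"time": t, "value": self.values})


@dataclass
class ModelOutput:
    """Predicted neural signal of a forward model, with pattern markers."""

    sample_rate: float
    values: np.ndarray
    pattern_onsets: np.ndarray
    source: str = "model"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.pattern_onsets = np.asarray(self.pattern_onsets, dtype=int)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("model output contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.size


@dataclass
class EEGRecording:
    """Multi-channel EEG block with pattern-onset events.

    ``data`` is channels x samples in microvolts. ``events`` holds the
    sample indices of pattern onsets. ``condition`` carries tempo and
    attention labels (free-form mapping).
    """

    sample_rate: float
    channels: tuple
    data: np.ndarray
    events: np.ndarray
    condition: dict = field(default_factory=dict)

    def __post_init__(self):
        self.channels = tuple(self.channels)
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.events = np.asarray(self.events, dtype=int)
        if self.data.shape[0] != len(self.channels):
            raise ValueError("data rows must match channel count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data contains non-finite values")
        if self.events.size > 1 and np.any(np.diff(self.events) <= 0):
            raise ValueError("events must be strictly increasing")
        missing = set(CLUSTER_CHANNELS) - set(self.channels)
        if missing:
            raise ValueError(f"missing cluster channels: {sorted(missing)}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def cluster_average(self, cluster=CLUSTER_CHANNELS) -> np.ndarray:
        idx = [self.channels.index(ch) for ch in cluster]
        return self.data[idx].mean(axis=0)

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            sample_rate=self.sample_rate,
            channels=np.array(self.channels),
            data=self.data,
            events=self.events,
            condition=np.array(sorted(self.condition.items()), dtype=object),
        )

    @classmethod
    def load(cls, path: str | Path) -> "EEGRecording":
        with np.load(path, allow_pickle=True) as f:
            condition = dict(f["condition"].tolist()) if f["condition"].size else {}
            return cls(
                sample_rate=float(f["sample_rate"]),
                channels=tuple(f["channels"].tolist()),
                data=f["data"],
                events=f["events"],
                condition=condition,
            )


def load_raw_eeg(path: str | Path, pattern_label: str,
                 condition: dict | None = None) -> EEGRecording:
    """Loader hook for real recordings in standard interchange formats.

    Reads BDF/EDF/FIF through MNE and maps annotations matching
    ``pattern_label`` to pattern-onset events. Preprocessing
    (re-referencing, interpolation, ICA) is expected to have been done
    upstream.
    """
    import mne

    raw = mne.io.read_raw(str(path), preload=True, verbose="error")
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    if pattern_label not in event_id:
        raise ValueError(f"annotation label {pattern_label!r} not found")
    onsets = events[events[:, 2] == event_id[pattern_label], 0]
    return EEGRecording(
        sample_rate=raw.info["sfreq"],
        channels=tuple(raw.ch_names),
        data=raw.get_data() * 1e6,
        events=onsets,
        condition=condition or {},
    )


def as_signal(obj) -> tuple[np.ndarray, float, np.ndarray]:
    """Coerce an EEGRecording / ModelOutput / Envelope to
    (1-D signal, sample_rate, pattern_onsets).

    EEG recordings are averaged over the fronto-central cluster.
    """
    if isinstance(obj, EEGRecording):
        return obj.cluster_average(), obj.sample_rate, obj.events
    if isinstance(obj, ModelOutput):
        return obj.values, obj.sample_rate, obj.pattern_onsets
    if isinstance(obj, Envelope):
        if obj.pattern_onsets is None:
            raise ValueError("envelope has no pattern-onset markers")
        return obj.values, obj.sample_rate, obj.pattern_onsets
    raise TypeError(f"cannot interpret {type(obj).__name__} as a signal")
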