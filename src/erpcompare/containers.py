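"""Core in-memory containers shared by all pipeline stages.

The pipeline operates on epoched multichannel EEG stored as plain
numpy tensors with explicit axis metadata.  ``EpochSet`` is the unit of
exchange between stages: one subject, one experimental cell
(condition x presentation), all trials.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = ["EpochSet", "TFRCube"]


@dataclass
class EpochSet:
    """Epoched EEG for one subject in one condition/presentation cell.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Voltage in microvolts.
    times : ndarray, shape (n_samples,)
        Time axis in seconds relative to stimulus onset (t = 0 is the
        onset of the door-opening event that reveals the object).
    sfreq : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        Montage channel names, one per channel, unique.
    condition : str
        Between-subject group label (e.g. ``"PC"``, ``"VR"``, ``"RL"``).
    presentation : int
        Within-subject presentation index (1 = first, 2 = second).
    subject_id : str
    flags : dict
        Free-form processing provenance (e.g. ``erp_subtracted``).
    """

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    channel_labels: tuple
    condition: str = ""
    presentation: int = 1
    subject_id: str = ""
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        n_trials, n_channels, n_samples = self.data.shape
        if len(self.channel_labels) != n_channels:
            raise ValueError("channel_labels length must match data axis 1")
        if len(set(self.channel_labels)) != n_channels:
            raise ValueError("channel labels must be unique")
        if self.times.shape != (n_samples,):
            raise ValueError("times length must match data axis 2")
        dt = np.diff(self.times)
        if n_samples > 1:
            if not np.all(dt > 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.sfreq, rtol=1e-6, atol=1e-9):
                raise ValueError("times must be uniformly spaced at 1/sfreq")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy_with(self, data: np.ndarray | None = None, **kwargs) -> "EpochSet":
        """Return a copy, optionally substituting the data tensor."""
        out = replace(self, **kwargs)
        if data is not None:
            out.data = np.asarray(data, dtype=float)
            if out.data.shape[1:] != (self.n_channels, self.n_samples):
                raise ValueError("replacement data has incompatible shape")
        else:
            out.data = self.data.copy()
        out.flags = dict(self.flags, **kwargs.get("flags", {}))
        return out

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label: {label!r}") from None

    def average(self) -> np.ndarray:
        """Trial-average waveform, shape (n_channels, n_samples)."""
        return self.data.mean(axis=0)


@dataclass
class TFRCube:
    """Trial-averaged time-frequency amplitude for one subject/cell.

    ``amplitude`` holds non-negative magnitudes (microvolts) on a
    frequencies x channels x samples grid.  ``mode`` records whether the
    per-trial ERP was subtracted before decomposition (``"induced"``) or
    the decomposition was run on the trial average (``"evoked"``).
    """

    amplitude: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channel_labels: tuple
    mode: str = "induced"
    condition: str = ""
    presentation: int = 1
    subject_id: str = ""
    band_meta: Mapping | None = None

    def __post_init__(self):
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        expected = (len(self.freqs), len(self.channel_labels), len(self.times))
        if self.amplitude.shape != expected:
            raise ValueError(
                f"amplitude shape {self.amplitude.shape} != (freqs, channels, samples) {expected}"
            )
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be non-negative magnitude")
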