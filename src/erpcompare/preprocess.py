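"""Preprocessing of epoched EEG.

Implements the deterministic part of the cleaning chain on
already-epoched data: deviant-channel detection and interpolation,
average reference, zero-phase FIR band-pass with linear detrending, and
pre-stimulus baseline correction.  Artifact-subspace and ICA-based
cleaning are represented only by :func:`clean_hook`, a user-swappable
pass-through, since they operate on continuous raw recordings with
external toolchains.

All operations preserve trial count, channel count and the time axis.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import signal

from .containers import EpochSet
from . import montage as _montage

__all__ = [
    "PreprocessConfig",
    "baseline_correct",
    "average_reference",
    "fir_bandpass_detrend",
    "flag_deviant_channels",
    "interpolate_channels",
    "clean_hook",
    "run_preprocess",
]


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``baseline_window_ms`` is the pre-stimulus interval whose mean is
    subtracted per trial and channel.  ``band_hz`` is the FIR pass band;
    ``numtaps`` sets the FIR length (odd, linear phase) and hence the
    transition bandwidth (~3.3/numtaps * sfreq for the Hamming design,
    about 6.6 Hz at 512 Hz with the default 257 taps).  ``deviant_k``
    is the SD-multiplier of the deviant-channel rule.
    """

    baseline_window_ms: Tuple[float, float] = (-500.0, -300.0)
    band_hz: Tuple[float, float] = (0.25, 30.0)
    deviant_k: float = 2.0
    numtaps: int = 257
    reference: str = "average"
    neighbor_k: int = 4

    def __post_init__(self):
        if self.band_hz[0] >= self.band_hz[1]:
            raise ValueError("band_hz must be (low, high) with low < high")
        if self.deviant_k <= 0:
            raise ValueError("deviant_k must be > 0")
        if self.numtaps % 2 == 0:
            raise ValueError("numtaps must be odd for a type-I linear-phase FIR")


def _window_slice(times: np.ndarray, window_ms: Tuple[float, float],
                  sfreq: float) -> np.ndarray:
    lo, hi = window_ms[0] / 1000.0, window_ms[1] / 1000.0
    if lo >= hi:
        raise ValueError("window must be (lo, hi) with lo < hi")
    eps = 1e-9  # float guard only; the window is closed, not nearest-sample
    if lo < times[0] - eps or hi > times[-1] + eps:
        raise ValueError(
            f"window ({window_ms[0]}, {window_ms[1]}) ms outside epoch "
            f"[{times[0] * 1000:.1f}, {times[-1] * 1000:.1f}] ms"
        )
    mask = (times >= lo - eps) & (times <= hi + eps)
    if not mask.any():
        raise ValueError("window contains no samples")
    return mask


def baseline_correct(epochs: EpochSet,
                     window_ms: Tuple[float, float] = (-500.0, -300.0)
                     ) -> EpochSet:
    """Subtract the mean over the pre-stimulus window, per trial/channel."""
    mask = _window_slice(epochs.times, window_ms, epochs.sfreq)
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    out = epochs.copy_with(data=epochs.data - base)
    out.flags["baseline_window_ms"] = tuple(window_ms)
    return out


def average_reference(epochs: EpochSet) -> EpochSet:
    """Re-reference to the instantaneous mean across channels."""
    if epochs.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    mean = epochs.data.mean(axis=1, keepdims=True)
    out = epochs.copy_with(data=epochs.data - mean)
    out.flags["reference"] = "average"
    return out


def _design_fir(band_hz: Tuple[float, float], sfreq: float,
                numtaps: int) -> np.ndarray:
    low, high = band_hz
    nyq = sfreq / 2.0
    if high >= nyq:
        raise ValueError(f"upper band edge {high} Hz is at/above Nyquist {nyq} Hz")
    if low <= 0:
        return signal.firwin(numtaps, high, fs=sfreq, pass_zero="lowpass")
    return signal.firwin(numtaps, [low, high], fs=sfreq, pass_zero="bandpass")


def fir_bandpass_detrend(epochs: EpochSet,
                         band_hz: Tuple[float, float] = (0.25, 30.0),
                         numtaps: int = 257) -> EpochSet:
    """Zero-phase FIR band-pass plus per-trial linear detrending.

    The linear-phase FIR is applied forward and backward (``filtfilt``),
    so the net phase response is zero and component peak latencies are
    not shifted -- essential for the latency analysis downstream.
    Detrending removes any residual linear drift the 0.25 Hz high-pass
    edge leaves within a 2 s epoch.
    """
    taps = _design_fir(band_hz, epochs.sfreq, numtaps)
    padlen = min(3 * len(taps), epochs.n_samples - 1)
    filt = signal.filtfilt(taps, [1.0], epochs.data, axis=-1, padlen=padlen)
    out_data = signal.detrend(filt, axis=-1, type="linear")
    out = epochs.copy_with(data=out_data)
    out.flags["band_hz"] = tuple(band_hz)
    return out


def channel_spread(epochs: EpochSet) -> np.ndarray:
    """Per-channel SD over all trials and samples (the deviance statistic)."""
    return epochs.data.std(axis=(0, 2))


def flag_deviant_channels(epochs: EpochSet, k: float = 2.0) -> List[str]:
    """Channels whose spread deviates more than ``k`` SDs from the rest.

    The per-channel statistic is the SD of the channel's data across
    trials and samples; a channel is flagged when that statistic lies
    more than ``k`` standard deviations (over channels) from the
    channel mean.  Deterministic.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    stat = channel_spread(epochs)
    mu, sd = stat.mean(), stat.std()
    if sd == 0:
        return []
    flagged = np.abs(stat - mu) > k * sd
    return [epochs.channel_labels[i] for i in np.nonzero(flagged)[0]]


def interpolate_channels(epochs: EpochSet, bad: Sequence[str],
                         neighbors: Mapping[str, Sequence[str]] | None = None
                         ) -> EpochSet:
    """Replace bad channels by the mean of their good neighbours.

    ``neighbors`` maps each channel to its adjacency list; by default a
    nearest-neighbour map is built from the template montage positions.
    Good channels are returned untouched (bit-identical).
    """
    bad = list(bad)
    unknown = [b for b in bad if b not in epochs.channel_labels]
    if unknown:
        raise KeyError(f"bad channels not in montage: {unknown}")
    if neighbors is None:
        neighbors = _montage.neighbor_map(epochs.channel_labels)
    data = epochs.data.copy()
    bad_set = set(bad)
    for ch in bad:
        good = [n for n in neighbors.get(ch, ()) if n not in bad_set
                and n in epochs.channel_labels]
        if not good:
            raise ValueError(f"channel {ch!r} has no good neighbour to "
                             "interpolate from")
        idx = [epochs.channel_index(n) for n in good]
        data[:, epochs.channel_index(ch), :] = epochs.data[:, idx, :].mean(axis=1)
    out = epochs.copy_with(data=data)
    out.flags["interpolated"] = tuple(bad)
    return out


def clean_hook(epochs: EpochSet,
               fn: Callable[[EpochSet], EpochSet] | None = None) -> EpochSet:
    """Pass-through slot for external artifact cleaning.

    The raw-data cleaning steps (artifact-subspace reconstruction, ICA
    component rejection) are assumed to have been applied upstream by
    their published tools; this hook is the identity unless a callable
    is supplied.
    """
    return epochs if fn is None else fn(epochs)


def run_preprocess(epochs: EpochSet,
                   config: PreprocessConfig | None = None,
                   clean: Callable[[EpochSet], EpochSet] | None = None
                   ) -> EpochSet:
    """Default chain: clean hook -> deviant detection -> interpolation ->
    average reference -> band-pass + detrend -> baseline."""
    cfg = config or PreprocessConfig()
    out = clean_hook(epochs, clean)
    bad = flag_deviant_channels(out, cfg.deviant_k)
    if bad:
        out = interpolate_channels(
            out, bad, _montage.neighbor_map(out.channel_labels, cfg.neighbor_k))
    out = average_reference(out)
    out = fir_bandpass_detrend(out, cfg.band_hz, cfg.numtaps)
    out = baseline_correct(out, cfg.baseline_window_ms)
    return out
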