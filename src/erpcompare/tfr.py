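"""Morlet wavelet time-frequency analysis of induced activity.

The induced (non-phase-locked) response is isolated by subtracting the
trial-average ERP from every trial, decomposing each trial with a bank
of Morlet wavelets, taking the magnitude per trial, and only then
averaging across trials.  Taking magnitudes before averaging is the
defining contract: activity with trial-varying phase survives it,
whereas it cancels from the trial average itself.

Wavelets are Gaussian-windowed complex exponentials with a fixed cycle
count, truncated to ``n_cycles / f`` seconds, zero-mean corrected, and
scaled so that a unit-amplitude sinusoid at the wavelet's frequency
reads out as amplitude 1 -- the transform therefore reports amplitude
in the input units (microvolts).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import signal

from .containers import EpochSet, TFRCube
from . import montage as _montage

__all__ = [
    "WaveletBank",
    "build_wavelets",
    "subtract_erp",
    "induced_tfr",
    "evoked_tfr",
    "extract_iabr",
    "edge_unreliable_mask",
]


@dataclass
class WaveletBank:
    freqs: np.ndarray
    n_cycles: float
    sfreq: float
    kernels: list  # complex ndarray per frequency, odd length

    def __len__(self) -> int:
        return len(self.freqs)

    def half_lengths_s(self) -> np.ndarray:
        """Kernel half-duration per frequency, n_cycles / (2 f) seconds."""
        return self.n_cycles / (2.0 * self.freqs)


def _morlet_kernel(f: float, n_cycles: float, sfreq: float) -> np.ndarray:
    half_n = int(round(n_cycles / (2.0 * f) * sfreq))
    t = np.arange(-half_n, half_n + 1) / sfreq
    sigma_t = n_cycles / (2.0 * np.pi * f)
    env = np.exp(-0.5 * (t / sigma_t) ** 2)
    carrier = np.exp(2j * np.pi * f * t)
    # Zero-mean correction (negligible at 12 cycles, exact nonetheless).
    kappa = np.sum(env * carrier) / np.sum(env)
    psi = env * (carrier - kappa)
    # Amplitude calibration: convolving with a unit-amplitude sinusoid at
    # f yields magnitude |sum(psi * e^{-i 2 pi f t})| / 2; divide it out
    # so a unit sinusoid reads out as amplitude 1.
    gain = np.abs(np.sum(psi * np.conj(carrier))) / 2.0
    return psi / gain


def build_wavelets(fmin: float = 1.0, fmax: float = 100.0, df: float = 0.5,
                   n_cycles: float = 12.0, sfreq: float = 512.0
                   ) -> WaveletBank:
    """Morlet bank on a regular frequency grid (defaults: 199 wavelets,
    1-100 Hz in 0.5 Hz steps, 12 cycles each)."""
    if fmax >= sfreq / 2.0:
        raise ValueError("fmax must be below Nyquist")
    if fmin <= 0 or df <= 0 or n_cycles <= 0:
        raise ValueError("fmin, df and n_cycles must be > 0")
    n = int(round((fmax - fmin) / df)) + 1
    freqs = fmin + df * np.arange(n)
    kernels = [_morlet_kernel(f, n_cycles, sfreq) for f in freqs]
    return WaveletBank(freqs=freqs, n_cycles=n_cycles, sfreq=sfreq,
                       kernels=kernels)


def subtract_erp(epochs: EpochSet) -> EpochSet:
    """Remove the phase-locked part: subtract the trial average per channel."""
    if epochs.n_trials < 2:
        raise ValueError("ERP subtraction needs at least 2 trials")
    out = epochs.copy_with(data=epochs.data - epochs.average()[None])
    out.flags["erp_subtracted"] = True
    return out


def _tfr_amplitude(data: np.ndarray, bank: WaveletBank,
                   trial_chunk: int = 16) -> np.ndarray:
    """Mean-over-trials magnitude of the wavelet transform.

    data: (n_trials, n_channels, n_samples) -> (n_freqs, n_channels,
    n_samples).  Trials are chunked to bound the size of the complex
    intermediate.
    """
    n_trials, n_channels, n_samples = data.shape
    out = np.zeros((len(bank), n_channels, n_samples))
    for fi, kernel in enumerate(bank.kernels):
        acc = np.zeros((n_channels, n_samples))
        for start in range(0, n_trials, trial_chunk):
            block = data[start:start + trial_chunk]
            conv = signal.fftconvolve(
                block.astype(complex), kernel[None, None, :],
                mode="same", axes=2)
            acc += np.abs(conv).sum(axis=0)
        out[fi] = acc / n_trials
    return out


def induced_tfr(epochs: EpochSet, bank: WaveletBank,
                allow_unsubtracted: bool = False) -> TFRCube:
    """Induced time-frequency amplitude: per-trial transform magnitudes,
    averaged across trials.

    Requires the input to be ERP-subtracted (``subtract_erp``); pass
    ``allow_unsubtracted=True`` to override, e.g. for single-trial
    oracle checks.
    """
    if not epochs.flags.get("erp_subtracted") and not allow_unsubtracted:
        raise ValueError(
            "epochs are not ERP-subtracted; run subtract_erp first or "
            "pass allow_unsubtracted=True")
    amp = _tfr_amplitude(epochs.data, bank)
    return TFRCube(amplitude=amp, freqs=bank.freqs, times=epochs.times,
                   channel_labels=epochs.channel_labels, mode="induced",
                   condition=epochs.condition,
                   presentation=epochs.presentation,
                   subject_id=epochs.subject_id)


def evoked_tfr(epochs: EpochSet, bank: WaveletBank) -> TFRCube:
    """Wavelet amplitude of the trial-average ERP (phase-locked part)."""
    amp = _tfr_amplitude(epochs.average()[None], bank)
    return TFRCube(amplitude=amp, freqs=bank.freqs, times=epochs.times,
                   channel_labels=epochs.channel_labels, mode="evoked",
                   condition=epochs.condition,
                   presentation=epochs.presentation,
                   subject_id=epochs.subject_id)


def edge_unreliable_mask(bank: WaveletBank, times: np.ndarray) -> np.ndarray:
    """Boolean (n_freqs, n_samples): True where edge effects can bias the
    amplitude.

    A sample is flagged when the epoch edge lies within two SDs of the
    kernel's Gaussian envelope (sigma_t = n_cycles / (2 pi f)), i.e.
    when more than ~2% of the kernel's mass overhangs the epoch.  The
    truncated kernel support is longer (n_cycles / (2 f) per side) but
    its extreme tails carry negligible energy."""
    times = np.asarray(times, float)
    two_sigma = (bank.n_cycles / (np.pi * bank.freqs))[:, None]
    return (times[None, :] < times[0] + two_sigma) | \
           (times[None, :] > times[-1] - two_sigma)


def extract_iabr(cube: TFRCube,
                 band_hz: Tuple[float, float] = (9.5, 12.0),
                 window_ms: Tuple[float, float] = (410.0, 970.0),
                 cluster: Sequence[str] | None = None,
                 baseline_window_ms: Tuple[float, float] = (-500.0, -300.0)
                 ) -> float:
    """Induced alpha-band response: one scalar per subject/cell.

    Amplitude is baseline-normalised subtractively per frequency and
    channel (mean over the pre-stimulus baseline window), then averaged
    over the frequency band x time window x posterior cluster.  A
    post-stimulus desynchronization therefore comes out negative.
    """
    if cluster is None:
        cluster = _montage.IABR_CORE_CLUSTER + _montage.IABR_NEIGHBOR_RING
    cluster = [c for c in dict.fromkeys(cluster)]
    missing = [c for c in cluster if c not in cube.channel_labels]
    if missing:
        raise KeyError(f"cluster channels not in cube: {missing}")
    fmask = (cube.freqs >= band_hz[0]) & (cube.freqs <= band_hz[1])
    if not fmask.any():
        raise ValueError(f"band {band_hz} Hz contains no bank frequencies")
    t = cube.times * 1000.0
    bmask = (t >= baseline_window_ms[0]) & (t <= baseline_window_ms[1])
    wmask = (t >= window_ms[0]) & (t <= window_ms[1])
    if not bmask.any() or not wmask.any():
        raise ValueError("baseline or analysis window outside the epoch")
    ch_idx = [cube.channel_labels.index(c) for c in cluster]
    amp = cube.amplitude
    baseline = amp[:, :, bmask].mean(axis=2, keepdims=True)
    norm = amp - baseline
    return float(norm[np.ix_(np.nonzero(fmask)[0], ch_idx,
                             np.nonzero(wmask)[0])].mean())
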