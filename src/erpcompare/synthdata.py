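"""Synthetic epoched EEG with the statistical structure the analysis assumes.

The generator emulates a three-group visual study: abstract objects shown
on a desktop monitor (PC), in immersive virtual reality (VR), or as real,
physical objects (RL), 33 subjects per group, 80 trials per subject, two
consecutive presentations of each object, 512 Hz sampling, epochs from
-500 ms to +1500 ms around stimulus (door-opening) onset.

Each trial is the sum of

* three Gaussian-windowed monophasic deflections standing in for the
  visual P1, N1 and P2 components, with condition-specific mean latencies
  and amplitudes, between-subject variability on both, and a small
  within-subject trial-to-trial latency jitter;
* non-phase-locked ~10 Hz alpha whose envelope dips after stimulus onset
  (event-related desynchronization), with a condition-specific depth;
* 1/f (pink) background noise, independent across channels.

Component and alpha activity are projected to the scalp through a smooth
occipito-parietal gain profile; no head-model forward solution is used.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Iterator, List, Tuple

import numpy as np

from .containers import EpochSet
from . import montage as _montage

__all__ = [
    "ComponentParams",
    "AlphaParams",
    "NoiseParams",
    "SimulationConfig",
    "default_config",
    "component_waveform",
    "alpha_activity",
    "desync_envelope",
    "pink_noise",
    "topography_weights",
    "simulate_subject",
    "simulate_study",
]

# FWHM -> Gaussian sigma conversion factor, 2*sqrt(2*ln 2).
_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))

CONDITIONS = ("PC", "VR", "RL")
COMPONENTS = ("P1", "N1", "P2")


@dataclass
class ComponentParams:
    """One ERP component in one condition.

    ``width_ms`` is the full width at half maximum of the Gaussian
    deflection.  ``mean_amplitude_uv`` carries the component's polarity
    in its sign (N1 negative).
    """

    mean_latency_ms: float
    sd_latency_ms: float
    mean_amplitude_uv: float
    sd_amplitude_uv: float
    width_ms: float

    def __post_init__(self):
        if self.sd_latency_ms < 0 or self.sd_amplitude_uv < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.width_ms <= 0:
            raise ValueError("width_ms must be > 0")


@dataclass
class AlphaParams:
    center_freq_hz: float = 10.0
    amplitude_uv: float = 3.0
    #: Fractional post-stimulus amplitude reduction, per condition.
    desync_depth: Dict[str, float] = field(
        default_factory=lambda: {"PC": 0.50, "VR": 0.55, "RL": 0.30}
    )
    desync_window_ms: Tuple[float, float] = (350.0, 1050.0)
    ramp_ms: float = 100.0

    def __post_init__(self):
        for name, d in self.desync_depth.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"desync depth for {name} must be in [0, 1]")


@dataclass
class NoiseParams:
    one_over_f_exponent: float = 1.0
    sd_uv: float = 2.0

    def __post_init__(self):
        if self.sd_uv < 0:
            raise ValueError("noise sd must be >= 0")


def _default_conditions() -> Dict[str, Dict[str, ComponentParams]]:
    # Latency means/SDs are the group-level values the analysis is meant
    # to recover; amplitudes are chosen to reproduce the qualitative
    # between-condition amplitude ordering (P1: PC > VR > RL; corrected
    # N1 most negative for PC; corrected P2 largest for VR).
    spec = {
        "PC": {
            "P1": (121.33, 12.31, 5.2, 1.8),
            "N1": (188.42, 10.13, -7.2, 2.0),
            "P2": (273.53, 20.85, 4.6, 2.2),
        },
        "VR": {
            "P1": (120.18, 22.20, 4.6, 1.8),
            "N1": (154.88, 15.45, -5.6, 2.0),
            "P2": (271.96, 25.24, 8.0, 2.2),
        },
        "RL": {
            "P1": (136.66, 22.38, 3.8, 1.8),
            "N1": (186.91, 8.95, -5.9, 2.0),
            "P2": (259.14, 26.25, 5.0, 2.2),
        },
    }
    widths = {"P1": 24.0, "N1": 32.0, "P2": 48.0}
    return {
        cond: {
            comp: ComponentParams(m, sd_l, a, sd_a, widths[comp])
            for comp, (m, sd_l, a, sd_a) in comps.items()
        }
        for cond, comps in spec.items()
    }


@dataclass
class SimulationConfig:
    conditions: Dict[str, Dict[str, ComponentParams]] = field(
        default_factory=_default_conditions
    )
    alpha: AlphaParams = field(default_factory=AlphaParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    n_subjects_per_condition: int = 33
    n_trials: int = 80
    n_presentations: int = 2
    sfreq: float = 512.0
    n_channels: int = 128
    epoch_window_ms: Tuple[float, float] = (-500.0, 1500.0)
    #: Within-subject trial-to-trial latency jitter (SD, ms), applied
    #: independently per component and trial.
    trial_jitter_sd_ms: float = 5.0
    seed: int = 0

    def __post_init__(self):
        t0, t1 = self.epoch_window_ms
        if not (t0 < 0.0 < t1):
            raise ValueError("epoch window must straddle stimulus onset")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be > 0")
        if self.trial_jitter_sd_ms < 0:
            raise ValueError("trial jitter SD must be >= 0")

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds; t = 0 is stimulus onset."""
        n = int(round((self.epoch_window_ms[1] - self.epoch_window_ms[0])
                      / 1000.0 * self.sfreq))
        return self.epoch_window_ms[0] / 1000.0 + np.arange(n) / self.sfreq

    @property
    def channel_labels(self) -> tuple:
        return _montage.default_montage(self.n_channels)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "conditions" in d:
            d["conditions"] = {
                cond: {c: ComponentParams(**p) for c, p in comps.items()}
                for cond, comps in d["conditions"].items()
            }
        if "alpha" in d:
            d["alpha"] = AlphaParams(**d["alpha"])
        if "noise" in d:
            d["noise"] = NoiseParams(**d["noise"])
        for key in ("epoch_window_ms",):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def default_config(**overrides) -> SimulationConfig:
    """Study-default simulation parameters, optionally overridden."""
    return SimulationConfig(**overrides)


# ---------------------------------------------------------------------------
# Primitive signal generators
# ---------------------------------------------------------------------------

def component_waveform(latency_ms: float, amplitude_uv: float, width_ms: float,
                       times: np.ndarray) -> np.ndarray:
    """Gaussian-windowed monophasic deflection on the given time axis.

    The deflection peaks (in signed value ``amplitude_uv``) at
    ``latency_ms``; ``width_ms`` is its FWHM.  Raises if the requested
    latency lies outside the time axis.
    """
    times = np.asarray(times, dtype=float)
    lat = latency_ms / 1000.0
    if not (times[0] <= lat <= times[-1]):
        raise ValueError(
            f"latency {latency_ms} ms outside time axis "
            f"[{times[0] * 1000:.1f}, {times[-1] * 1000:.1f}] ms"
        )
    if width_ms <= 0:
        raise ValueError("width_ms must be > 0")
    sigma = width_ms / 1000.0 / _FWHM
    return amplitude_uv * np.exp(-0.5 * ((times - lat) / sigma) ** 2)


def desync_envelope(times: np.ndarray, window_ms: Tuple[float, float],
                    depth: float, ramp_ms: float = 100.0) -> np.ndarray:
    """Amplitude envelope: 1 outside the window, 1-depth inside it.

    Edges ramp with a raised-cosine of ``ramp_ms`` so the dip carries no
    broadband transient.
    """
    times_ms = np.asarray(times, dtype=float) * 1000.0
    lo, hi = window_ms
    env = np.ones_like(times_ms)

    def smooth(x):  # 0 -> 1 raised-cosine step over [0, 1]
        x = np.clip(x, 0.0, 1.0)
        return 0.5 - 0.5 * np.cos(np.pi * x)

    if ramp_ms > 0:
        dip = smooth((times_ms - (lo - ramp_ms)) / ramp_ms) \
            * smooth(((hi + ramp_ms) - times_ms) / ramp_ms)
    else:
        dip = ((times_ms >= lo) & (times_ms <= hi)).astype(float)
    return env - depth * dip


def alpha_activity(freq_hz: float, envelope: np.ndarray, times: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """One trial of non-phase-locked oscillatory activity.

    A unit sinusoid at ``freq_hz`` with a uniformly random phase per
    call, amplitude-modulated by ``envelope``.  The random phase is what
    makes the activity induced rather than evoked: it survives
    single-trial amplitude averaging but cancels in the trial average.
    """
    if freq_hz <= 0:
        raise ValueError("freq_hz must be > 0")
    phase = rng.uniform(0.0, 2.0 * np.pi)
    return np.asarray(envelope, float) * np.sin(
        2.0 * np.pi * freq_hz * np.asarray(times, float) + phase
    )


def pink_noise(n_samples: int, exponent: float, sd: float,
               rng: np.random.Generator, shape: tuple = ()) -> np.ndarray:
    """Zero-mean 1/f**exponent noise, sample SD normalised to ``sd``.

    ``shape`` prepends leading axes (e.g. ``(n_trials, n_channels)``);
    traces are independent along them.  Spectral shaping is done by
    filtering white Gaussian noise in the frequency domain with
    amplitude f**(-exponent/2); the DC bin is zeroed.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    full = tuple(shape) + (n_samples,)
    if sd == 0:
        return np.zeros(full)
    white = rng.standard_normal(full)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * gain, n=n_samples, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    s = x.std(axis=-1, keepdims=True)
    s[s == 0] = 1.0
    return x * (sd / s)


def topography_weights(component: str, channel_labels,
                       cluster=None, spatial_sigma: float = 0.7) -> np.ndarray:
    """Smooth scalp gain profile for a signal source, in [0, 1].

    Gains fall off as a Gaussian of chordal distance from the centroid
    of the source's electrode cluster (occipito-parietal for all three
    ERP components and for alpha), normalised to a maximum of 1.
    """
    labels = list(channel_labels)
    if cluster is None:
        cluster = (_montage.IABR_CORE_CLUSTER if component == "alpha"
                   else _montage.ERP_ROI)
    if len(labels) == 1:
        return np.ones(1)
    xyz = _montage.channel_positions(labels)  # validates labels
    in_cluster = [c for c in cluster if c in labels]
    if not in_cluster:
        raise ValueError("montage contains no channel of the source cluster")
    centroid = _montage.channel_positions(in_cluster).mean(axis=0)
    centroid /= np.linalg.norm(centroid)
    d = np.linalg.norm(xyz - centroid, axis=1)
    w = np.exp(-0.5 * (d / spatial_sigma) ** 2)
    return w / w.max()


# ---------------------------------------------------------------------------
# Subject- and study-level simulation
# ---------------------------------------------------------------------------

def _draw_amplitude(p: ComponentParams, rng: np.random.Generator) -> float:
    """Between-subject amplitude draw, truncated to preserve polarity.

    A plain normal with the default means/SDs would give a small
    fraction of subjects a sign-flipped component, which no real
    recording shows and which degenerates peak picking; the draw is
    therefore truncated at 20% of the mean magnitude on the zero side.
    """
    mean, sd = p.mean_amplitude_uv, p.sd_amplitude_uv
    if sd == 0 or mean == 0:
        return mean
    from scipy import stats as sps
    bound = 0.2 * mean
    if mean > 0:
        a, b = (bound - mean) / sd, np.inf
    else:
        a, b = -np.inf, (bound - mean) / sd
    return float(sps.truncnorm.rvs(a, b, loc=mean, scale=sd,
                                   random_state=rng))

def subject_rng(config: SimulationConfig, condition: str,
                subject_index: int) -> np.random.Generator:
    """Independent, reproducible random stream for one subject.

    Streams derive from (master seed, condition index, subject index)
    through a SeedSequence, so subjects are independent and any subject
    can be regenerated without simulating the others.
    """
    ci = CONDITIONS.index(condition) if condition in CONDITIONS else \
        sorted(config.conditions).index(condition)
    ss = np.random.SeedSequence(entropy=(int(config.seed), ci, int(subject_index)))
    return np.random.default_rng(ss)


def simulate_subject(config: SimulationConfig, condition: str,
                     rng: np.random.Generator,
                     subject_id: str = "S00") -> List[EpochSet]:
    """Simulate all epochs for one subject: one EpochSet per presentation.

    Between-subject variability: a single standard-normal factor shifts
    all three component latencies (scaled by each component's latency
    SD), reflecting shared individual differences in processing speed;
    amplitudes are drawn independently per component.  Both are drawn
    once per subject and shared across trials and presentations.
    """
    if condition not in config.conditions:
        raise KeyError(f"unknown condition {condition!r}")
    comps = config.conditions[condition]
    times = config.times
    labels = config.channel_labels
    n_samp = times.size

    z_lat = rng.standard_normal()
    lat = {c: p.mean_latency_ms + p.sd_latency_ms * z_lat
           for c, p in comps.items()}
    amp = {c: _draw_amplitude(p, rng) for c, p in comps.items()}

    topo = {c: topography_weights(c, labels) for c in comps}
    topo["alpha"] = topography_weights("alpha", labels)
    depth = config.alpha.desync_depth.get(condition, 0.0)
    env = desync_envelope(times, config.alpha.desync_window_ms, depth,
                          config.alpha.ramp_ms)

    out = []
    for pres in range(1, config.n_presentations + 1):
        data = np.zeros((config.n_trials, len(labels), n_samp))
        for c, p in comps.items():
            jit = rng.normal(0.0, config.trial_jitter_sd_ms,
                             size=config.n_trials)
            sigma = p.width_ms / 1000.0 / _FWHM
            centers = (lat[c] + jit)[:, None] / 1000.0
            wav = amp[c] * np.exp(-0.5 * ((times[None, :] - centers) / sigma) ** 2)
            data += wav[:, None, :] * topo[c][None, :, None]
        if config.alpha.amplitude_uv > 0:
            phases = rng.uniform(0.0, 2.0 * np.pi, size=config.n_trials)
            osc = np.sin(2.0 * np.pi * config.alpha.center_freq_hz
                         * times[None, :] + phases[:, None]) * env[None, :]
            data += (config.alpha.amplitude_uv * osc)[:, None, :] \
                * topo["alpha"][None, :, None]
        data += pink_noise(n_samp, config.noise.one_over_f_exponent,
                           config.noise.sd_uv, rng,
                           shape=(config.n_trials, len(labels)))
        out.append(EpochSet(
            data=data, times=times, sfreq=config.sfreq,
            channel_labels=labels, condition=condition,
            presentation=pres, subject_id=subject_id,
            flags={"drawn_latency_ms": dict(lat),
                   "drawn_amplitude_uv": dict(amp)},
        ))
    return out


def simulate_study(config: SimulationConfig) -> Iterator[EpochSet]:
    """Yield EpochSets for every subject x condition x presentation.

    Subjects are numbered uniquely across conditions so that subject IDs
    are usable as the between-subject unit in the statistics stage.
    """
    for ci, condition in enumerate(sorted(config.conditions)):
        for si in range(config.n_subjects_per_condition):
            sid = f"{condition}{si + 1:02d}"
            rng = subject_rng(config, condition, si)
            yield from simulate_subject(config, condition, rng, subject_id=sid)
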