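import numpy as np
import pytest

from erpcompare import synthdata as syn
from erpcompare.containers import EpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def times_512():
    """Default epoch time axis: -500..+1500 ms at 512 Hz."""
    return -0.5 + np.arange(1024) / 512.0


@pytest.fixture
def tiny_config():
    """Small but structurally complete simulation: full ROI montage,
    few subjects/trials, all stochastic layers active."""
    return syn.default_config(n_channels=9, n_subjects_per_condition=2,
                              n_trials=8, seed=99)


@pytest.fixture
def deterministic_config():
    """All randomness off: no noise, no alpha, no jitter, no
    between-subject spread.  Trials are identical by construction."""
    cfg = syn.default_config(n_channels=9, n_subjects_per_condition=1,
                             n_trials=3, seed=0, trial_jitter_sd_ms=0.0)
    cfg.noise.sd_uv = 0.0
    cfg.alpha.amplitude_uv = 0.0
    for cond in cfg.conditions:
        for p in cfg.conditions[cond].values():
            p.sd_latency_ms = 0.0
            p.sd_amplitude_uv = 0.0
    return cfg


def make_epochs(data, sfreq=512.0, t0=-0.5, labels=None, **kw):
    data = np.asarray(data, dtype=float)
    n_samples = data.shape[-1]
    times = t0 + np.arange(n_samples) / sfreq
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(data.shape[1]))
    return EpochSet(data=data, times=times, sfreq=sfreq,
                    channel_labels=labels, **kw)


@pytest.fixture
def make_epochset():
    return make_epochs
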