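"""ERP component quantification.

Grand averages per condition x presentation, an RMS time course to
localise components without biasing toward any condition, ROI-based
peak latency per component, latency-corrected mean-peak amplitude
(peak +/- 15 ms), and peak-to-peak correction of the N1 and P2 against
their preceding component.

Measurement conventions:

* amplitude is always read out at each cell's own peak latency, so
  between-condition latency differences do not contaminate amplitude
  comparisons;
* extremum ties resolve to the earliest sample;
* latencies are reported at sample resolution (no sub-sample
  interpolation).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import EpochSet
from . import montage as _montage

__all__ = [
    "ComponentSpec",
    "default_components",
    "grand_average",
    "rms_timecourse",
    "rms_peak_latencies",
    "roi_mean",
    "peak_latency",
    "mean_peak_amplitude",
    "peak_to_peak",
    "subject_peaks",
    "build_peak_table",
]


@dataclass(frozen=True)
class ComponentSpec:
    """Definition of one ERP component for peak measurement."""

    name: str
    polarity: str  # "positive" | "negative"
    search_window_ms: Tuple[float, float]
    roi: Tuple[str, ...] = _montage.ERP_ROI

    def __post_init__(self):
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")
        lo, hi = self.search_window_ms
        if not lo < hi:
            raise ValueError("search window must be non-degenerate (lo < hi)")


def default_components(roi: Sequence[str] = _montage.ERP_ROI
                       ) -> List[ComponentSpec]:
    """P1/N1/P2 with search windows bracketing typical posterior latencies.

    Windows (P1 70-170, N1 110-230, P2 200-330 ms) cover the
    between-condition latency range each component can plausibly take in
    this paradigm, with margin for between-subject spread.
    """
    roi = tuple(roi)
    return [
        ComponentSpec("P1", "positive", (70.0, 170.0), roi),
        ComponentSpec("N1", "negative", (110.0, 230.0), roi),
        ComponentSpec("P2", "positive", (200.0, 330.0), roi),
    ]


def grand_average(epochsets: Iterable[EpochSet]
                  ) -> Dict[Tuple[str, int], np.ndarray]:
    """Grand-average ERP per (condition, presentation) cell.

    Two-level average: trials within subject first, then subjects within
    cell, so every subject contributes equally regardless of trial count.
    Returns channel x sample arrays keyed by cell.
    """
    per_subject: Dict[Tuple[str, int], list] = {}
    for es in epochsets:
        if es.n_trials < 1:
            raise ValueError("every cell needs at least one trial")
        key = (es.condition, es.presentation)
        per_subject.setdefault(key, []).append(es.average())
    if not per_subject:
        raise ValueError("no epochsets given")
    return {key: np.mean(subs, axis=0) for key, subs in per_subject.items()}


def rms_timecourse(erps: Iterable[np.ndarray]) -> np.ndarray:
    """RMS across electrodes of the across-cell mean ERP.

    The cell ERPs (channels x samples) are first averaged across cells,
    then at each sample the root of the mean squared amplitude over
    electrodes is taken.  Non-negative by construction.
    """
    erps = list(erps)
    if not erps:
        raise ValueError("no ERPs given")
    mean_erp = np.mean(erps, axis=0)
    return np.sqrt(np.mean(mean_erp ** 2, axis=0))


def _window_mask(times: np.ndarray, window_ms: Tuple[float, float],
                 sfreq: float) -> np.ndarray:
    lo, hi = window_ms[0] / 1000.0, window_ms[1] / 1000.0
    eps = 1e-9  # float guard; the window is closed, not nearest-sample
    if lo < times[0] - eps or hi > times[-1] + eps:
        raise ValueError(f"window {window_ms} ms outside the time axis")
    mask = (times >= lo - eps) & (times <= hi + eps)
    if not mask.any():
        raise ValueError(f"window {window_ms} ms contains no samples")
    return mask


def rms_peak_latencies(rms: np.ndarray, times: np.ndarray,
                       specs: Sequence[ComponentSpec],
                       sfreq: float) -> Dict[str, float]:
    """Latency (ms) of the maximal RMS within each component's window."""
    out = {}
    for spec in specs:
        mask = _window_mask(times, spec.search_window_ms, sfreq)
        idx = np.nonzero(mask)[0]
        seg = rms[idx]
        out[spec.name] = float(times[idx[np.argmax(seg)]] * 1000.0)
    return out


def roi_mean(erp: np.ndarray, channel_labels: Sequence[str],
             roi: Sequence[str]) -> np.ndarray:
    """Unweighted mean waveform over the ROI channels."""
    roi = list(roi)
    if not roi:
        raise ValueError("ROI is empty")
    labels = list(channel_labels)
    missing = [r for r in roi if r not in labels]
    if missing:
        raise KeyError(f"ROI channels not in montage: {missing}")
    idx = [labels.index(r) for r in roi]
    return np.asarray(erp)[idx].mean(axis=0)


def peak_latency(waveform: np.ndarray, times: np.ndarray,
                 spec: ComponentSpec, sfreq: float) -> float:
    """Latency (ms) of the signed extremum within the search window.

    Maximum for positive components, minimum for negative ones; ties go
    to the earliest sample (np.argmax/argmin convention).
    """
    mask = _window_mask(times, spec.search_window_ms, sfreq)
    idx = np.nonzero(mask)[0]
    seg = np.asarray(waveform)[idx]
    j = np.argmax(seg) if spec.polarity == "positive" else np.argmin(seg)
    return float(times[idx[j]] * 1000.0)


def mean_peak_amplitude(waveform: np.ndarray, times: np.ndarray,
                        peak_latency_ms: float, sfreq: float,
                        halfwidth_ms: float = 15.0) -> float:
    """Mean amplitude over the closed window peak +/- halfwidth.

    Raises if the window would be clipped by the epoch edge rather than
    silently truncating it.
    """
    window = (peak_latency_ms - halfwidth_ms, peak_latency_ms + halfwidth_ms)
    mask = _window_mask(times, window, sfreq)
    return float(np.asarray(waveform)[mask].mean())


def peak_to_peak(p1: float, n1: float, p2: float) -> Tuple[float, float, float]:
    """Peak-to-peak correction of mean-peak amplitudes.

    The P1 stands on the baseline and is kept as-is; the N1 is expressed
    relative to the preceding P1 level and the P2 relative to the
    preceding N1 level, removing carry-over of absolute amplitude.
    """
    return (p1, n1 - p1, p2 - n1)


def subject_peaks(es_first: EpochSet, es_second: EpochSet | None,
                  specs: Sequence[ComponentSpec],
                  ) -> List[dict]:
    """Peak rows for one subject: per presentation x component.

    For each presentation the trial-average ROI waveform is measured:
    per component the peak latency within its search window, the mean
    amplitude at that latency +/- 15 ms, and the peak-to-peak corrected
    amplitude.
    """
    rows = []
    for es in filter(None, (es_first, es_second)):
        wave = roi_mean(es.average(), es.channel_labels, specs[0].roi)
        lat = {s.name: peak_latency(wave, es.times, s, es.sfreq) for s in specs}
        raw = {s.name: mean_peak_amplitude(wave, es.times, lat[s.name], es.sfreq)
               for s in specs}
        corr = dict(zip(("P1", "N1", "P2"),
                        peak_to_peak(raw.get("P1", 0.0), raw.get("N1", 0.0),
                                     raw.get("P2", 0.0))))
        for s in specs:
            rows.append({
                "subject": es.subject_id,
                "condition": es.condition,
                "presentation": es.presentation,
                "component": s.name,
                "peak_latency_ms": lat[s.name],
                "raw_amplitude_uv": raw[s.name],
                "corrected_amplitude_uv": corr.get(s.name, raw[s.name]),
            })
    return rows


def build_peak_table(epochsets: Iterable[EpochSet],
                     specs: Sequence[ComponentSpec] | None = None
                     ) -> pd.DataFrame:
    """PeakTable over a whole study: one row per
    subject x condition x presentation x component."""
    specs = list(specs) if specs is not None else default_components()
    rows = []
    for es in epochsets:
        rows.extend(subject_peaks(es, None, specs))
    if not rows:
        raise ValueError("no epochsets given")
    df = pd.DataFrame(rows)
    dup = df.duplicated(["subject", "condition", "presentation", "component"])
    if dup.any():
        raise ValueError("duplicate subject/presentation/component cells")
    return df
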