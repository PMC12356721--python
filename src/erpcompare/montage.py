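"""Montage handling: channel labels, 3-D positions, and sensor clusters.

The simulated recordings use extended 10-10/10-5 electrode names so that
the posterior regions of interest can be addressed by their conventional
labels (O1, Oz, POz, ...).  Positions come from the standard 10-05
template montage and are only used for (a) smooth scalp topographies in
the generator and (b) neighbour maps for channel interpolation; no
forward modelling is attempted.
"""
from __future__ import annotations

import functools
import warnings

import numpy as np

__all__ = [
    "ERP_ROI",
    "IABR_CORE_CLUSTER",
    "IABR_NEIGHBOR_RING",
    "default_montage",
    "channel_positions",
    "neighbor_map",
]

#: Occipito-parietal ROI used for component peak measurement.
ERP_ROI = ("O1", "Oz", "O2", "PO3", "POz", "PO4", "P3", "Pz", "P4")

#: Named posterior cluster for the induced alpha-band response.
IABR_CORE_CLUSTER = (
    "Pz", "POz", "Oz", "O1", "O2",
    "P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8", "P9", "P10",
)

#: Fourteen electrodes ringing the core cluster; included by default.
IABR_NEIGHBOR_RING = (
    "PO3", "PO4", "PO7", "PO8", "CP1", "CP2", "CP3", "CP4",
    "CP5", "CP6", "CPz", "TP7", "TP8", "Iz",
)

# Non-posterior anchors guaranteed to be present in every montage size,
# so frontal/central contrast channels exist for tests and topographies.
_ANCHORS = ("Fz", "Cz", "Fp1", "Fp2", "F3", "F4", "C3", "C4", "T7", "T8")

_PRIORITY = tuple(
    dict.fromkeys(ERP_ROI + IABR_CORE_CLUSTER + IABR_NEIGHBOR_RING + _ANCHORS)
)


@functools.lru_cache(maxsize=1)
def _template_positions() -> dict:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mon = mne.channels.make_standard_montage("standard_1005")
        pos = mon.get_positions()["ch_pos"]
    # Unit-normalise to the scalp sphere so distances are scale-free.
    out = {}
    for name, xyz in pos.items():
        xyz = np.asarray(xyz, dtype=float)
        n = np.linalg.norm(xyz)
        if n > 0:
            out[name] = xyz / n
    return out


def default_montage(n_channels: int = 128) -> tuple:
    """Deterministic list of ``n_channels`` electrode labels.

    Posterior ROI/cluster channels come first so that reduced montages
    (used to keep simulations light) always contain the sensors the
    analysis needs; the rest fills up in template order.
    """
    pos = _template_positions()
    labels = [p for p in _PRIORITY if p in pos]
    if n_channels < len(ERP_ROI):
        raise ValueError(
            f"montage must contain the {len(ERP_ROI)}-channel ERP ROI; "
            f"got n_channels={n_channels}"
        )
    for name in pos:
        if len(labels) >= n_channels:
            break
        if name not in labels:
            labels.append(name)
    if len(labels) < n_channels:
        raise ValueError(f"template montage has only {len(labels)} labels")
    return tuple(labels[:n_channels])


def channel_positions(labels) -> np.ndarray:
    """Unit-sphere 3-D positions for the given labels, shape (n, 3)."""
    pos = _template_positions()
    out = np.empty((len(labels), 3))
    for i, name in enumerate(labels):
        if name not in pos:
            raise KeyError(f"unknown channel label: {name!r}")
        out[i] = pos[name]
    return out


def neighbor_map(labels, k: int = 4) -> dict:
    """Adjacency map: each label -> its ``k`` nearest neighbours.

    Used by channel interpolation.  Distances are chordal distances on
    the unit scalp sphere.
    """
    labels = list(labels)
    xyz = channel_positions(labels)
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    out = {}
    k_eff = min(k, len(labels) - 1)
    for i, name in enumerate(labels):
        order = np.argsort(d[i])[:k_eff]
        out[name] = tuple(labels[j] for j in order)
    return out
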