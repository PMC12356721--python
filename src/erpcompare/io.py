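"""HDF5 containers for epoched EEG and TFR cubes, plus config files.

Layout of an epoch container::

    /epochs/<subject_id>/p<presentation>/data     (trials, channels, samples)
    /epochs/<subject_id>/p<presentation>/times    (samples,)
    ... attrs: sfreq, condition, presentation, subject_id, flags (JSON)
    /channel_labels                               (channels,) UTF-8
    root attrs: seed, config (JSON), package version

Round-trips are lossless (float64 end to end).
"""
from __future__ import annotations

import json
from typing import Iterable, Iterator

import h5py
import numpy as np
import yaml

from .containers import EpochSet, TFRCube

__all__ = [
    "write_epochs", "read_epochs", "write_tfr", "read_tfr",
    "load_yaml", "dump_yaml", "SchemaError",
]


class SchemaError(RuntimeError):
    """Raised when a container file lacks a required dataset/attribute."""


def _label_ds(value):
    return np.array([s.encode() for s in value])


def write_epochs(path, epochsets: Iterable[EpochSet], seed=None,
                 config: dict | None = None) -> None:
    epochsets = list(epochsets)
    if not epochsets:
        raise ValueError("nothing to write")
    with h5py.File(path, "w") as f:
        f.create_dataset("channel_labels",
                         data=_label_ds(epochsets[0].channel_labels))
        if seed is not None:
            f.attrs["seed"] = int(seed)
        if config is not None:
            f.attrs["config"] = json.dumps(config)
        grp = f.create_group("epochs")
        for es in epochsets:
            g = grp.require_group(es.subject_id).create_group(
                f"p{es.presentation}")
            g.create_dataset("data", data=es.data, compression="gzip",
                             compression_opts=1)
            g.create_dataset("times", data=es.times)
            g.attrs["sfreq"] = float(es.sfreq)
            g.attrs["condition"] = es.condition
            g.attrs["presentation"] = int(es.presentation)
            g.attrs["subject_id"] = es.subject_id
            g.attrs["flags"] = json.dumps(es.flags, default=str)


def read_epochs(path) -> Iterator[EpochSet]:
    """Yield EpochSets from a container; raises SchemaError on malformed
    files."""
    with h5py.File(path, "r") as f:
        if "channel_labels" not in f or "epochs" not in f:
            raise SchemaError(f"{path}: missing channel_labels or epochs")
        labels = tuple(s.decode() for s in f["channel_labels"][()])
        for sid in sorted(f["epochs"]):
            sub = f["epochs"][sid]
            for pres in sorted(sub):
                g = sub[pres]
                for req in ("data", "times"):
                    if req not in g:
                        raise SchemaError(
                            f"{path}: /epochs/{sid}/{pres} lacks '{req}'")
                if "sfreq" not in g.attrs:
                    raise SchemaError(
                        f"{path}: /epochs/{sid}/{pres} lacks sfreq")
                yield EpochSet(
                    data=g["data"][()], times=g["times"][()],
                    sfreq=float(g.attrs["sfreq"]),
                    channel_labels=labels,
                    condition=str(g.attrs.get("condition", "")),
                    presentation=int(g.attrs.get("presentation", 1)),
                    subject_id=str(g.attrs.get("subject_id", sid)),
                    flags=json.loads(g.attrs.get("flags", "{}")),
                )


def write_tfr(path, cubes: Iterable[TFRCube]) -> None:
    cubes = list(cubes)
    if not cubes:
        raise ValueError("nothing to write")
    with h5py.File(path, "w") as f:
        f.create_dataset("channel_labels",
                         data=_label_ds(cubes[0].channel_labels))
        f.create_dataset("freqs", data=cubes[0].freqs)
        f.create_dataset("times", data=cubes[0].times)
        grp = f.create_group("tfr")
        for cube in cubes:
            g = grp.require_group(cube.subject_id).create_group(
                f"p{cube.presentation}")
            g.create_dataset("amplitude", data=cube.amplitude,
                             compression="gzip", compression_opts=1)
            g.attrs["mode"] = cube.mode
            g.attrs["condition"] = cube.condition
            g.attrs["presentation"] = int(cube.presentation)
            g.attrs["subject_id"] = cube.subject_id
            if cube.band_meta:
                g.attrs["band_meta"] = json.dumps(dict(cube.band_meta))


def read_tfr(path) -> Iterator[TFRCube]:
    with h5py.File(path, "r") as f:
        for req in ("channel_labels", "freqs", "times", "tfr"):
            if req not in f:
                raise SchemaError(f"{path}: missing '{req}'")
        labels = tuple(s.decode() for s in f["channel_labels"][()])
        freqs, times = f["freqs"][()], f["times"][()]
        for sid in sorted(f["tfr"]):
            for pres in sorted(f["tfr"][sid]):
                g = f["tfr"][sid][pres]
                meta = g.attrs.get("band_meta")
                yield TFRCube(
                    amplitude=g["amplitude"][()], freqs=freqs, times=times,
                    channel_labels=labels, mode=str(g.attrs.get("mode", "")),
                    condition=str(g.attrs.get("condition", "")),
                    presentation=int(g.attrs.get("presentation", 1)),
                    subject_id=str(g.attrs.get("subject_id", sid)),
                    band_meta=json.loads(meta) if meta else None,
                )


def load_yaml(path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    return out or {}


def dump_yaml(path, obj: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
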