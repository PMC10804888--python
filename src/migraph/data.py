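"""Labelled epoched-EEG containers and their on-disk (HDF5) form.

A :class:`TrialSet` is the package's canonical in-memory container: a
``(trials, channels, samples)`` signal array plus labels, sampling rate,
channel names, subject ids and class names.  The on-disk form is a single
HDF5 file carrying the same arrays plus a provenance JSON blob recording
every transformation applied (generator spec, filters, graph embedding).

Epoching convention used throughout: half-open sample windows
``[start*fs, end*fs)`` with 0-based sample indexing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = ["TrialSet", "read_container", "write_container"]

CONTAINER_VERSION = "1"


@dataclass
class TrialSet:
    """Epoched multichannel EEG trials with labels.

    Parameters
    ----------
    signals : (n_trials, n_channels, n_samples) float array, microvolts.
    labels : (n_trials,) integer class ids in ``[0, n_classes)``.
    fs : sampling rate in Hz.
    channel_names : ordered channel names; the order must match whatever
        montage layout is used downstream.
    subject_ids : (n_trials,) integer subject of each trial.
    class_names : ordered class labels.
    provenance : free-form record of how the set was produced/transformed.
    """

    signals: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    subject_ids: np.ndarray
    class_names: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids, dtype=np.int64)
        self.channel_names = tuple(self.channel_names)
        self.class_names = tuple(self.class_names)
        if self.signals.ndim != 3:
            raise ValueError(f"signals must be 3-D (trials, channels, samples), got {self.signals.shape}")
        n = self.signals.shape[0]
        if self.labels.shape != (n,):
            raise ValueError("labels length does not match trial count")
        if self.subject_ids.shape != (n,):
            raise ValueError("subject_ids length does not match trial count")
        if self.signals.shape[1] != len(self.channel_names):
            raise ValueError(
                f"{self.signals.shape[1]} signal channels vs {len(self.channel_names)} channel names"
            )
        if n and (self.labels.min() < 0 or self.labels.max() >= len(self.class_names)):
            raise ValueError("labels out of range for class_names")

    @property
    def n_trials(self) -> int:
        return self.signals.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[2]

    def with_signals(self, signals: np.ndarray, note: dict | None = None) -> "TrialSet":
        """Copy with replaced signals and an appended provenance note."""
        prov = dict(self.provenance)
        if note:
            prov.setdefault("history", [])
            prov["history"] = list(prov["history"]) + [note]
        return replace(self, signals=signals, provenance=prov)

    def check_channels(self, expected: tuple[str, ...]) -> None:
        """Raise if channel order differs from ``expected``, naming the first mismatch."""
        if len(self.channel_names) != len(expected):
            raise ValueError(
                f"channel count mismatch: container has {len(self.channel_names)}, "
                f"expected {len(expected)}"
            )
        for k, (got, want) in enumerate(zip(self.channel_names, expected)):
            if got != want:
                raise ValueError(f"channel order mismatch at position {k}: {got!r} != {want!r}")


def write_container(trials: TrialSet, path) -> None:
    """Write a TrialSet to a single HDF5 container (lossless round-trip)."""
    with h5py.File(path, "w") as f:
        f.attrs["version"] = CONTAINER_VERSION
        f.attrs["fs"] = float(trials.fs)
        f.attrs["channel_names"] = json.dumps(list(trials.channel_names))
        f.attrs["class_names"] = json.dumps(list(trials.class_names))
        f.attrs["provenance"] = json.dumps(trials.provenance)
        f.create_dataset("signals", data=trials.signals)
        f.create_dataset("labels", data=trials.labels)
        f.create_dataset("subject_ids", data=trials.subject_ids)


def read_container(path) -> TrialSet:
    """Read a TrialSet container, validating version and schema."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("version")
        if version != CONTAINER_VERSION:
            raise ValueError(f"container version {version!r} != supported {CONTAINER_VERSION!r}")
        for key in ("signals", "labels", "subject_ids"):
            if key not in f:
                raise ValueError(f"container missing dataset {key!r}")
        for key in ("fs", "channel_names", "class_names", "provenance"):
            if key not in f.attrs:
                raise ValueError(f"container missing attribute {key!r}")
        return TrialSet(
            signals=f["signals"][...],
            labels=f["labels"][...],
            fs=float(f.attrs["fs"]),
            channel_names=tuple(json.loads(f.attrs["channel_names"])),
            subject_ids=f["subject_ids"][...],
            class_names=tuple(json.loads(f.attrs["class_names"])),
            provenance=json.loads(f.attrs["provenance"]),
        )
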