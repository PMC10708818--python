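"""Core domain containers: recordings, event tables, and epochs.

A :class:`Recording` is a continuous multichannel EEG signal; an
:class:`EventTable` holds task-onset markers; an :class:`Epoch` is one
trial's slice, running from 1 s before task onset to 15 s after it
(16 s total).  Recordings round-trip through a self-describing ``.npz``
container for synthetic data and load from EDF/BDF via MNE for real
acquisitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The closed set of mental-task labels of the seven-task protocol:
#: mental rotation, word generation, mental subtraction, mental singing,
#: mental navigation, motor imagery, and face imagery.
TASKS: tuple[str, ...] = ("ROT", "WORD", "SUB", "SING", "NAV", "MI", "FACE")

#: Default epoch bounds relative to task onset, seconds (half-open).
EPOCH_T_START = -1.0
EPOCH_T_END = 15.0


@dataclass
class Recording:
    """Continuous multichannel signal with channel metadata.

    Parameters
    ----------
    channel_labels
        Unique channel names, one per data row.
    fs
        Sampling rate in Hz, > 0.
    data
        Real matrix, shape (n_channels, n_samples).
    montage
        Optional mapping label -> 2D/3D scalp position.
    reference
        Free-text tag describing the current reference.
    """

    channel_labels: list[str]
    fs: float
    data: np.ndarray
    montage: dict[str, tuple[float, ...]] | None = None
    reference: str = "as-recorded"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) matrix")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in recording "
                f"(have {self.channel_labels})"
            ) from None

    def copy_with(self, **kwargs) -> "Recording":
        return replace(self, **kwargs)


@dataclass
class EventTable:
    """Task-onset markers: one row per trial."""

    table: pd.DataFrame  # columns onset_s, task, participant, session

    REQUIRED = ("onset_s", "task", "participant", "session")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"event table missing columns {missing}")
        onsets = self.table["onset_s"].to_numpy(dtype=float)
        if len(onsets) and onsets.min() < 0:
            raise ValueError("event onsets must be >= 0")
        if not np.all(np.diff(onsets) > 0):
            raise ValueError("event onsets must be strictly increasing")
        bad = set(self.table["task"]) - set(TASKS)
        if bad:
            raise ValueError(f"unknown task labels {sorted(bad)}; allowed: {TASKS}")

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_rows(cls, rows) -> "EventTable":
        """Build from an iterable of (onset_s, task, participant, session)."""
        return cls(pd.DataFrame(rows, columns=list(cls.REQUIRED)))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "EventTable":
        return cls(pd.read_csv(path))


@dataclass
class Epoch:
    """One trial's signal slice on the time axis [-1, 15) s around onset."""

    signal: np.ndarray  # (channels x samples)
    fs: float
    channel_labels: list[str]
    task: str
    participant: str
    session: str
    trial: int
    t0: float = EPOCH_T_START

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("epoch signal must be 2-D")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to task onset."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epoch") from None


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path) -> None:
    """Write a Recording to the internal self-describing container (.npz)."""
    path = Path(path)
    meta = {
        "labels": np.array(rec.channel_labels, dtype=object),
        "fs": np.array(rec.fs),
        "data": rec.data,
        "reference": np.array(rec.reference, dtype=object),
    }
    if rec.montage is not None:
        meta["montage_labels"] = np.array(sorted(rec.montage), dtype=object)
        meta["montage_pos"] = np.array(
            [rec.montage[k] for k in sorted(rec.montage)], dtype=float
        )
    np.savez(path, **meta)


def read_recording(path, format: str = "auto") -> Recording:
    """Read a Recording from disk.

    Parameters
    ----------
    path
        File path.
    format
        ``"EDF"``, ``"BDF"``, ``"internal"`` (the package's .npz
        container), or ``"auto"`` to infer from the extension.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    if fmt == "auto":
        ext = path.suffix.lower()
        fmt = {".edf": "edf", ".bdf": "bdf", ".npz": "internal"}.get(ext, "")
        if not fmt:
            raise ValueError(
                f"cannot infer format from extension {ext!r}; pass format="
            )
    if fmt == "internal":
        with np.load(path, allow_pickle=True) as z:
            labels = [str(x) for x in z["labels"]]
            montage = None
            if "montage_labels" in z:
                montage = {
                    str(k): tuple(p)
                    for k, p in zip(z["montage_labels"], z["montage_pos"])
                }
            return Recording(
                channel_labels=labels,
                fs=float(z["fs"]),
                data=z["data"],
                montage=montage,
                reference=str(z["reference"]),
            )
    if fmt in ("edf", "bdf"):
        import mne

        reader = mne.io.read_raw_edf if fmt == "edf" else mne.io.read_raw_bdf
        raw = reader(path, preload=True, verbose="error")
        labels = list(raw.ch_names)
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate channel labels in {path}")
        return Recording(
            channel_labels=labels,
            fs=float(raw.info["sfreq"]),
            data=raw.get_data(),
            reference="as-recorded",
        )
    raise ValueError(f"unknown format {format!r}")
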