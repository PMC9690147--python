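"""Reading, normalizing and assembling Bonn-style single-channel EEG data.

The on-disk dialect is the one the University of Bonn corpus ships: plain
ASCII, one sample value per line, one file per recording, one directory per
class.  Amplitudes are min-max normalized to [0, 1] per record before any
downstream modelling.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical class labels, in fixed order (healthy = Bonn set A,
#: interictal = set D, ictal = set E).
CLASSES: tuple[str, str, str] = ("healthy", "interictal", "ictal")

#: Nominal Bonn sampling rate in Hz.
BONN_FS = 173.61

#: Working signal length; the 4097-sample Bonn records are trimmed by one
#: sample so strided convolutions halve the length cleanly.
DEFAULT_LENGTH = 4096


class DegenerateSignalError(ValueError):
    """Raised when a signal is constant (zero amplitude range)."""


@dataclass(frozen=True)
class EegRecord:
    """One single-channel EEG signal with its class label.

    Parameters
    ----------
    samples : ndarray
        Amplitude vector; unitless once normalized to [0, 1].
    fs : float
        Sampling rate in Hz (metadata only; nothing downstream depends on it).
    label : str
        One of :data:`CLASSES`.
    record_id : str
        Unique identifier, typically the source filename stem.
    """

    samples: np.ndarray
    fs: float
    label: str
    record_id: str

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.label not in CLASSES:
            raise ValueError(f"unknown class label {self.label!r}; expected one of {CLASSES}")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class EegDataset:
    """An ordered collection of :class:`EegRecord` with unique ids."""

    records: list[EegRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.label] = counts.get(r.label, 0) + 1
        return counts

    def subset(self, label: str) -> "EegDataset":
        """Records of a single class, order preserved."""
        return EegDataset([r for r in self.records if r.label == label])

    def matrix(self) -> np.ndarray:
        """Stack all signals into an (n_records, length) array."""
        return np.stack([r.samples for r in self.records])

    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def manifest(self) -> pd.DataFrame:
        """Per-record summary table (id, label, length, amplitude range)."""
        return pd.DataFrame(
            {
                "record_id": [r.record_id for r in self.records],
                "label": [r.label for r in self.records],
                "n_samples": [len(r) for r in self.records],
                "min": [float(r.samples.min()) for r in self.records],
                "max": [float(r.samples.max()) for r in self.records],
            }
        )


def read_bonn_file(path: str | os.PathLike) -> np.ndarray:
    """Read one ASCII recording: one sample per line, blank lines ignored.

    Returns the raw amplitude vector in file order, unnormalized.
    Raises ``ValueError`` naming the offending line for non-numeric content
    and for empty files.
    """
    path = Path(path)
    values: list[float] = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            try:
                values.append(float(stripped))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: cannot parse {stripped!r} as a number"
                ) from None
    if not values:
        raise ValueError(f"{path}: file contains no samples")
    return np.asarray(values, dtype=np.float64)


def write_bonn_file(path: str | os.PathLike, samples: Sequence[float]) -> None:
    """Write a sample vector in the one-value-per-line ASCII dialect.

    Uses ``repr`` formatting so a read round trip reproduces the values
    exactly.
    """
    arr = np.asarray(samples, dtype=np.float64)
    with open(path, "w") as fh:
        for v in arr:
            fh.write(f"{float(v)!r}\n")


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Affinely map a signal onto [0, 1]: ``(x - min) / (max - min)``.

    Raises :class:`DegenerateSignalError` for constant signals.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError(f"need at least 2 samples to normalize, got {x.size}")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateSignalError("constant signal: amplitude range is zero")
    return (x - lo) / (hi - lo)


def trim_to_length(x: np.ndarray, length: int) -> np.ndarray:
    """Return the first ``length`` samples of ``x``."""
    x = np.asarray(x)
    if length <= 0:
        raise ValueError(f"length must be positive, got {length}")
    if x.size < length:
        raise ValueError(f"signal has {x.size} samples, fewer than requested {length}")
    return x[:length]


def load_dataset(
    root: str | os.PathLike,
    class_map: Mapping[str, str],
    length: int = DEFAULT_LENGTH,
    fs: float = BONN_FS,
) -> EegDataset:
    """Load a directory-per-class tree into a normalized dataset.

    Parameters
    ----------
    root : path
        Directory containing one subdirectory per class.
    class_map : mapping
        Subdirectory name -> class label (a member of :data:`CLASSES`).
    length : int
        Working length; every record is trimmed to its first ``length``
        samples before normalization.
    fs : float
        Sampling rate recorded as metadata.

    Files within each directory are read in lexicographic filename order so
    two loads of the same tree produce identical datasets.
    """
    root = Path(root)
    missing = [d for d in class_map if not (root / d).is_dir()]
    if missing:
        raise FileNotFoundError(f"missing class directories under {root}: {sorted(missing)}")
    records: list[EegRecord] = []
    for dirname in sorted(class_map):
        label = class_map[dirname]
        files = sorted(p for p in (root / dirname).iterdir() if p.is_file())
        if not files:
            raise FileNotFoundError(f"no files in class directory {root / dirname}")
        for p in files:
            raw = read_bonn_file(p)
            samples = minmax_normalize(trim_to_length(raw, length))
            records.append(
                EegRecord(samples=samples, fs=fs, label=label, record_id=f"{dirname}/{p.stem}")
            )
    return EegDataset(records)


def write_dataset(
    root: str | os.PathLike, dataset: EegDataset, dir_map: Mapping[str, str] | None = None
) -> None:
    """Write a dataset as a directory-per-class ASCII tree.

    ``dir_map`` maps class label -> directory name; defaults to the label
    itself.  Record ids become filenames (any directory prefix stripped).
    """
    root = Path(root)
    dir_map = dir_map or {c: c for c in CLASSES}
    for rec in dataset:
        d = root / dir_map[rec.label]
        d.mkdir(parents=True, exist_ok=True)
        name = rec.record_id.split("/")[-1]
        write_bonn_file(d / f"{name}.txt", rec.samples)
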