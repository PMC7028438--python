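"""Record containers, persistence, lead selection, windowing and batching.

Records are kept as [n_leads x T] float matrices in millivolts with an
ordered list of lead names and a two-level label pair.  Persistence uses an
HDF5 container (dataset ``signals`` [N x leads x T] float32, attributes
``fs`` and ``lead_names``) plus a CSV manifest with one row per record
(record_id, task1, task2, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .taxonomy import (
    InvalidLabelError,
    TASK1_CLASSES,
    TASK1_INDEX,
    TASK2_CLASSES,
    TASK2_INDEX,
    map_task2_to_task1,
)

__all__ = [
    "LabelPair", "ECGRecord", "WindowedBatch", "FormatError",
    "write_dataset", "read_dataset", "select_leads", "window_record",
    "make_batches",
]


class FormatError(ValueError):
    """Raised when a container does not match the expected schema."""


@dataclass(frozen=True)
class LabelPair:
    """Coarse (5-class) and fine (15-class) diagnosis labels for one record."""

    task1: str
    task2: str

    def __post_init__(self):
        if self.task2 not in TASK2_CLASSES:
            raise InvalidLabelError(f"unknown fine label {self.task2!r}")
        if self.task1 not in TASK1_CLASSES:
            raise InvalidLabelError(f"unknown coarse label {self.task1!r}")
        if self.task1 != map_task2_to_task1(self.task2):
            raise InvalidLabelError(
                f"label hierarchy violation: {self.task2} belongs to "
                f"{map_task2_to_task1(self.task2)}, not {self.task1}")

    @classmethod
    def from_task2(cls, task2: str) -> "LabelPair":
        return cls(map_task2_to_task1(task2), task2)


@dataclass
class ECGRecord:
    """A multi-lead ECG signal with sampling rate, lead names and labels."""

    signal: np.ndarray          # [n_leads, T] in mV
    fs: float                   # Hz
    lead_names: tuple[str, ...]
    labels: LabelPair
    record_id: str
    seed: int | None = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.lead_names = tuple(self.lead_names)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a [n_leads, T] matrix")
        if self.signal.shape[0] < 2:
            raise ValueError("a record needs at least 2 leads")
        if self.signal.shape[1] < 1:
            raise ValueError("a record needs at least 1 sample")
        if len(self.lead_names) != self.signal.shape[0]:
            raise ValueError("lead_names length must match the lead axis")
        if len(set(self.lead_names)) != len(self.lead_names):
            raise ValueError("lead names must be unique")
        if not np.isfinite(self.signal).all():
            raise ValueError("signal contains NaN or Inf")

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class WindowedBatch:
    """A mini-batch of fixed-length windows with integer labels per task."""

    inputs: np.ndarray          # [M, n_leads, L_win]
    labels1: np.ndarray         # [M] indices into TASK1_CLASSES
    labels2: np.ndarray         # [M] indices into TASK2_CLASSES
    record_ids: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return self.inputs.shape[0]


# -- persistence ---------------------------------------------------------------

def _manifest_path(h5_path: Path) -> Path:
    return h5_path.with_suffix(".csv")


def write_dataset(records: Sequence[ECGRecord], path: str | Path,
                  manifest_path: str | Path | None = None) -> Path:
    """Write records to an HDF5 container and a CSV manifest next to it."""
    if not records:
        raise ValueError("no records to write")
    path = Path(path)
    manifest_path = Path(manifest_path) if manifest_path else _manifest_path(path)
    fs = records[0].fs
    leads = records[0].lead_names
    n_samp = records[0].n_samples
    for r in records:
        if r.fs != fs or r.lead_names != leads or r.n_samples != n_samp:
            raise ValueError("all records in a container must share fs, leads and length")
    signals = np.stack([r.signal for r in records]).astype(np.float32)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("signals", data=signals)
        ds.attrs["fs"] = fs
        ds.attrs["lead_names"] = list(leads)
    manifest = pd.DataFrame({
        "record_id": [r.record_id for r in records],
        "task1": [r.labels.task1 for r in records],
        "task2": [r.labels.task2 for r in records],
        "seed": [-1 if r.seed is None else r.seed for r in records],
    })
    manifest.to_csv(manifest_path, index=False)
    return path


def read_dataset(path: str | Path,
                 manifest_path: str | Path | None = None
                 ) -> tuple[list[ECGRecord], pd.DataFrame]:
    """Read a container written by :func:`write_dataset`.

    Labels are re-validated against the coarse/fine hierarchy on read.
    """
    path = Path(path)
    manifest_path = Path(manifest_path) if manifest_path else _manifest_path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        if "signals" not in f:
            raise FormatError(f"{path} has no 'signals' dataset")
        ds = f["signals"]
        if "fs" not in ds.attrs or "lead_names" not in ds.attrs:
            raise FormatError(f"{path} is missing fs/lead_names attributes")
        signals = np.asarray(ds, dtype=np.float64)
        fs = float(ds.attrs["fs"])
        leads = tuple(str(x) for x in ds.attrs["lead_names"])
    manifest = pd.read_csv(manifest_path)
    required = {"record_id", "task1", "task2", "seed"}
    if not required.issubset(manifest.columns):
        raise FormatError(f"manifest is missing columns {required - set(manifest.columns)}")
    if len(manifest) != signals.shape[0]:
        raise FormatError("manifest row count does not match signal count")
    records = []
    for i, row in manifest.iterrows():
        labels = LabelPair(str(row["task1"]), str(row["task2"]))  # validates hierarchy
        seed = int(row["seed"])
        records.append(ECGRecord(
            signal=signals[i], fs=fs, lead_names=leads, labels=labels,
            record_id=str(row["record_id"]), seed=None if seed < 0 else seed))
    return records, manifest


# -- lead selection and windowing ----------------------------------------------

def select_leads(record: ECGRecord, lead_names: Sequence[str]) -> ECGRecord:
    """Return a record restricted to ``lead_names``, in the requested order."""
    lead_names = tuple(lead_names)
    if len(lead_names) < 2:
        raise ValueError("at least 2 leads are required")
    missing = [name for name in lead_names if name not in record.lead_names]
    if missing:
        raise ValueError(f"leads not present in record: {missing}")
    rows = [record.lead_names.index(name) for name in lead_names]
    return ECGRecord(
        signal=record.signal[rows].copy(), fs=record.fs, lead_names=lead_names,
        labels=record.labels, record_id=record.record_id, seed=record.seed)


def window_record(record_or_signal, l_win: int, policy: str = "decimate") -> np.ndarray:
    """Reduce a [n_leads, T] signal to a fixed [n_leads, l_win] window.

    ``"crop-center"`` takes the centered ``l_win`` samples, zero-padding
    symmetrically when the record is shorter.  ``"decimate"`` resamples the
    whole record to ``l_win`` samples (polyphase filtering), preserving
    slow features such as ST-segment shifts at reduced rate.
    """
    signal = record_or_signal.signal if isinstance(record_or_signal, ECGRecord) \
        else np.asarray(record_or_signal, dtype=np.float64)
    if l_win < 1:
        raise ValueError("l_win must be >= 1")
    n_samples = signal.shape[1]
    if policy == "crop-center":
        if n_samples == l_win:
            return signal.copy()
        if n_samples > l_win:
            start = (n_samples - l_win) // 2
            return signal[:, start:start + l_win].copy()
        pad = l_win - n_samples
        left = pad // 2
        return np.pad(signal, ((0, 0), (left, pad - left)))
    if policy == "decimate":
        if n_samples == l_win:
            return signal.copy()
        g = np.gcd(l_win, n_samples)
        return resample_poly(signal, l_win // g, n_samples // g, axis=1)
    raise ValueError(f"unknown windowing policy {policy!r}")


def make_batches(records: Sequence[ECGRecord], batch_size: int, *,
                 l_win: int = 1900, policy: str = "decimate",
                 shuffle: bool = False, seed: int | None = None
                 ) -> Iterator[WindowedBatch]:
    """Yield windowed mini-batches covering every record exactly once.

    Order is deterministic: the input order, or a seeded permutation when
    ``shuffle`` is set.  The final partial batch is kept.
    """
    if not records:
        raise ValueError("empty dataset")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    order = np.arange(len(records))
    if shuffle:
        order = np.random.default_rng(seed).permutation(order)
    for start in range(0, len(records), batch_size):
        chunk = [records[i] for i in order[start:start + batch_size]]
        inputs = np.stack([window_record(r, l_win, policy) for r in chunk])
        yield WindowedBatch(
            inputs=inputs,
            labels1=np.array([TASK1_INDEX[r.labels.task1] for r in chunk]),
            labels2=np.array([TASK2_INDEX[r.labels.task2] for r in chunk]),
            record_ids=[r.record_id for r in chunk],
        )
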