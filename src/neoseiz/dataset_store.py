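"""Sample-matrix / tensor assembly and HDF5 dataset files.

Chunks are first laid side by side in a 2-D matrix of 18+1 rows: rows 1–18
hold the bipolar channels, the 19th row repeats each chunk's class label
(1 seizure / 0 non-seizure) across its column block. For ten 6-second chunks
at 64 Hz this matrix is 19 × 3840. For training, the matrix is rearranged —
no value altered — into a tensor of shape (n_chunks, window·fs, 18) plus a
label vector, and stored in HDF5 under the naming convention
``expert_<XXX>_<YYY>sec_<ZZZ>chunk_<VVV>Hz.hdf5``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .windowing import ChunkSet

N_MONTAGE_CHANNELS = 18

_NAME_RE = re.compile(
    r"^expert_(?P<expert>.+)_(?P<window>\d+)sec_(?P<chunks>\d+)chunk_(?P<fs>\d+)Hz\.hdf5$"
)


@dataclass
class TensorDataset:
    """The on-disk training payload: data (n, window·fs, 18) and labels (n,)."""

    data: np.ndarray
    labels: np.ndarray
    expert: str
    window: int
    chunks: int
    fs: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.data.ndim != 3 or self.data.shape[2] != N_MONTAGE_CHANNELS:
            raise ValueError(
                f"data must have shape (n, time, {N_MONTAGE_CHANNELS}), "
                f"got {self.data.shape}"
            )
        if self.data.shape[0] != len(self.labels):
            raise ValueError("labels length must match the sample axis")
        if self.data.shape[1] != self.window * self.fs:
            raise ValueError(
                f"time axis {self.data.shape[1]} != window·fs = {self.window * self.fs}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def filename(self) -> str:
        return dataset_filename(self.expert, self.window, self.chunks, self.fs)


def dataset_filename(expert: str, window: int, chunks: int, fs: int) -> str:
    """``expert_<XXX>_<YYY>sec_<ZZZ>chunk_<VVV>Hz.hdf5``."""
    return f"expert_{expert}_{window}sec_{chunks}chunk_{fs}Hz.hdf5"


def parse_dataset_filename(name: str) -> tuple[str, int, int, int]:
    """Inverse of :func:`dataset_filename`; raises on non-conforming names."""
    m = _NAME_RE.match(Path(name).name)
    if not m:
        raise ValueError(
            f"file name {name!r} does not match "
            "'expert_XXX_YYYsec_ZZZchunk_VVVHz.hdf5'"
        )
    return (m["expert"], int(m["window"]), int(m["chunks"]), int(m["fs"]))


# ---------------------------------------------------------------------------
# matrix <-> tensor


def assemble_matrix(cs: ChunkSet) -> np.ndarray:
    """Stack chunks left-to-right into the (18+1)-row sample matrix."""
    wfs = cs.params.samples_per_chunk
    matrix = np.zeros((N_MONTAGE_CHANNELS + 1, len(cs) * wfs))
    for i, chunk in enumerate(cs.chunks):
        if chunk.data.shape != (N_MONTAGE_CHANNELS, wfs):
            raise ValueError(
                f"chunk {i} has shape {chunk.data.shape}, "
                f"expected ({N_MONTAGE_CHANNELS}, {wfs})"
            )
        block = slice(i * wfs, (i + 1) * wfs)
        matrix[:N_MONTAGE_CHANNELS, block] = chunk.data
        matrix[N_MONTAGE_CHANNELS, block] = chunk.label
    return matrix


def to_tensor(
    matrix: np.ndarray,
    window: int,
    fs: int,
    expert: str = "",
    chunks: int = 0,
) -> TensorDataset:
    """Rearrange the sample matrix into (n, window·fs, 18) + label vector.

    ``tensor[n, t, c] == matrix[c, n·window·fs + t]``; the label of sample
    ``n`` is the (constant) value of the class row over its column block.
    """
    if matrix.shape[0] != N_MONTAGE_CHANNELS + 1:
        raise ValueError(f"matrix must have 19 rows, got {matrix.shape[0]}")
    wfs = window * fs
    if matrix.shape[1] % wfs != 0:
        raise ValueError(
            f"column count {matrix.shape[1]} not divisible by window·fs = {wfs}"
        )
    n = matrix.shape[1] // wfs
    blocks = matrix[:N_MONTAGE_CHANNELS].reshape(N_MONTAGE_CHANNELS, n, wfs)
    tensor = blocks.transpose(1, 2, 0)
    label_row = matrix[N_MONTAGE_CHANNELS].reshape(n, wfs)
    if n and not (label_row == label_row[:, :1]).all():
        bad = int(np.flatnonzero(~(label_row == label_row[:, :1]).all(axis=1))[0])
        raise ValueError(f"class row not constant within chunk block {bad}")
    labels = label_row[:, 0] if n else np.zeros(0)
    if n and not np.isin(labels, (0, 1)).all():
        raise ValueError("class row contains values outside {0, 1}")
    return TensorDataset(
        data=tensor, labels=labels, expert=expert, window=window,
        chunks=chunks, fs=fs,
    )


def from_matrix_free(ds: TensorDataset) -> np.ndarray:
    """Inverse rearrangement: tensor + labels back to the 19-row matrix."""
    n, wfs, _ = ds.data.shape
    matrix = np.zeros((N_MONTAGE_CHANNELS + 1, n * wfs))
    matrix[:N_MONTAGE_CHANNELS] = ds.data.transpose(2, 0, 1).reshape(
        N_MONTAGE_CHANNELS, n * wfs
    )
    matrix[N_MONTAGE_CHANNELS] = np.repeat(ds.labels, wfs)
    return matrix


def chunkset_to_dataset(cs: ChunkSet, expert: str) -> TensorDataset:
    """Full route chunk collection → matrix → tensor dataset."""
    return to_tensor(
        assemble_matrix(cs),
        window=cs.params.window,
        fs=cs.params.fs,
        expert=expert,
        chunks=cs.params.chunks,
    )


# ---------------------------------------------------------------------------
# HDF5 I/O


def write_hdf5(ds: TensorDataset, directory: str | Path, cs: ChunkSet | None = None) -> Path:
    """Write the dataset (and optional provenance sidecars) under ``directory``.

    Layout: datasets ``data`` (float32) and ``labels`` (int8), metadata as
    root attributes. When the originating chunk collection is given, two CSV
    sidecars (``seizures_*`` / ``non_seizures_*``) record which subject and
    start second each chunk came from.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / ds.filename
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=ds.data, dtype="float32")
        fh.create_dataset("labels", data=ds.labels, dtype="int8")
        fh.attrs["expert"] = ds.expert
        fh.attrs["window"] = ds.window
        fh.attrs["chunks"] = ds.chunks
        fh.attrs["fs"] = ds.fs
    if cs is not None:
        stem = path.stem
        for prefix, chunks in (
            ("seizures_", cs.positives),
            ("non_seizures_", cs.negatives),
        ):
            pd.DataFrame(
                [
                    {"subject": c.subject_id, "start_s": c.start_s, "origin": c.origin}
                    for c in chunks
                ]
            ).to_csv(directory / f"{prefix}{stem}.csv", index=False)
    return path


def read_hdf5(path: str | Path) -> TensorDataset:
    """Read a dataset file; the name must follow the naming convention."""
    path = Path(path)
    expert, window, chunks, fs = parse_dataset_filename(path.name)
    with h5py.File(path, "r") as fh:
        data = fh["data"][...]
        labels = fh["labels"][...]
    return TensorDataset(
        data=data, labels=labels, expert=expert, window=window, chunks=chunks, fs=fs
    )
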