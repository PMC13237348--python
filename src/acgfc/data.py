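"""Core containers: structural connectome, epoched ROI time series, trial table.

The structural connectome is a binary undirected graph over cortical regions
(ROIs); it is consumed as data, never estimated here. Epoched signals are
real-valued ROI time courses locked to a cue, with a binary condition label
(0 = repeat, 1 = switch) and a subject identifier per epoch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ROIAtlas",
    "Connectome",
    "EpochSet",
    "TrialTable",
    "read_connectome",
    "write_connectome",
    "read_epochs",
    "write_epochs",
    "read_trials",
    "write_trials",
]


@dataclass(frozen=True)
class ROIAtlas:
    """Ordered region labels; hemispheric regions carry a '.L'/'.R' suffix."""

    labels: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("atlas labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown ROI label: {label!r}") from None

    @classmethod
    def generic(cls, n: int) -> "ROIAtlas":
        """Synthetic hemispheric atlas: ROI01.L ... ROI{n/2}.L then .R."""
        half = (n + 1) // 2
        labels = [f"ROI{i + 1:02d}.L" for i in range(half)]
        labels += [f"ROI{i + 1:02d}.R" for i in range(n - half)]
        return cls(tuple(labels))


@dataclass(frozen=True)
class Connectome:
    """Binary undirected structural graph with labelled nodes.

    ``adjacency`` is symmetric with zero diagonal; ``edges`` lists undirected
    pairs (i, j) with i < j in row-major order. The graph acts as the spatial
    prior A over which all message passing and attribution is defined.
    """

    adjacency: np.ndarray
    atlas: ROIAtlas

    def __post_init__(self):
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if A.shape[0] != len(self.atlas):
            raise ValueError("atlas size does not match adjacency dimension")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        object.__setattr__(self, "adjacency", A.astype(np.int8))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edges(self) -> list[tuple[int, int]]:
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(iu.tolist(), ju.tolist()))

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    @property
    def density(self) -> float:
        n = self.n_nodes
        return 2.0 * self.n_edges / (n * (n - 1))

    def edge_labels(self) -> list[tuple[str, str]]:
        lab = self.atlas.labels
        return [(lab[i], lab[j]) for i, j in self.edges]

    @classmethod
    def from_edges(
        cls, n_nodes: int, edges: Sequence[tuple[int, int]], atlas: ROIAtlas | None = None
    ) -> "Connectome":
        A = np.zeros((n_nodes, n_nodes), dtype=np.int8)
        for i, j in edges:
            if i == j:
                raise ValueError("self-loops are not structural edges")
            A[i, j] = A[j, i] = 1
        return cls(A, atlas or ROIAtlas.generic(n_nodes))


def _binarize(A: np.ndarray) -> np.ndarray:
    if not np.isin(A, (0, 1)).all():
        logger.warning("non-binary adjacency thresholded at > 0")
        A = (A > 0).astype(np.int8)
    return A.astype(np.int8)


def read_connectome(path: str | Path, fmt: str | None = None) -> Connectome:
    """Read a connectome from an edge-list TSV or a labelled adjacency TSV.

    Edge lists have columns ``source_label  target_label`` (an optional third
    weight column is ignored after binarization); duplicate and reversed pairs
    are merged. Matrix files carry the label header row and column. Asymmetric
    matrix input is repaired by logical OR with a logged warning.
    """
    path = Path(path)
    if fmt is None:
        with open(path) as fh:
            first = fh.readline()
        ncols = len(first.rstrip("\n").split("\t"))
        fmt = "edgelist" if ncols <= 3 else "matrix"
    if fmt == "edgelist":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        labels = sorted(set(df[0]).union(df[1]), key=str)
        atlas = ROIAtlas(tuple(labels))
        n = len(labels)
        A = np.zeros((n, n), dtype=np.int8)
        for _, row in df.iterrows():
            i, j = atlas.index_of(row[0]), atlas.index_of(row[1])
            if i == j:
                raise ValueError(f"self-loop on {row[0]!r} is not a valid structural edge")
            A[i, j] = A[j, i] = 1
        return Connectome(A, atlas)
    if fmt == "matrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.shape[0] != df.shape[1]:
            raise ValueError(f"adjacency matrix is not square: {df.shape}")
        labels = tuple(str(c) for c in df.columns)
        if list(df.index.astype(str)) != list(labels):
            raise ValueError("matrix row labels do not match column labels")
        A = _binarize(df.to_numpy())
        if not np.array_equal(A, A.T):
            logger.warning("asymmetric adjacency input symmetrized by logical OR")
            A = ((A + A.T) > 0).astype(np.int8)
        np.fill_diagonal(A, 0)
        return Connectome(A, ROIAtlas(labels))
    raise ValueError(f"unknown connectome format: {fmt!r}")


def write_connectome(conn: Connectome, path: str | Path, fmt: str = "edgelist") -> None:
    path = Path(path)
    if fmt == "edgelist":
        with open(path, "w") as fh:
            for a, b in conn.edge_labels():
                fh.write(f"{a}\t{b}\n")
    elif fmt == "matrix":
        df = pd.DataFrame(conn.adjacency, index=conn.atlas.labels, columns=conn.atlas.labels)
        df.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown connectome format: {fmt!r}")


@dataclass
class EpochSet:
    """Cue-locked epochs: ``data`` is (epochs, nodes, samples) [, features].

    ``t0_ms`` is the time of the first sample relative to cue onset; the time
    axis is ``t0_ms + 1000 * arange(T) / fs``.
    """

    data: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    fs: float
    t0_ms: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be (epochs, nodes, samples[, features])")
        self.labels = np.asarray(self.labels)
        self.subjects = np.asarray(self.subjects)
        if self.labels.shape[0] != self.data.shape[0]:
            raise ValueError("labels length does not match number of epochs")
        if self.subjects.shape[0] != self.data.shape[0]:
            raise ValueError("subjects length does not match number of epochs")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary {0, 1}")
        if any(str(s) == "" for s in self.subjects):
            raise ValueError("subject IDs must be non-empty")
        self.labels = self.labels.astype(np.int8)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + 1000.0 * np.arange(self.n_samples) / self.fs

    def crop_ms(self, t_start: float, t_end: float) -> "EpochSet":
        """Restrict to samples with t_start <= t < t_end (ms, half-open)."""
        t = self.times_ms
        mask = (t >= t_start) & (t < t_end)
        if not mask.any():
            raise ValueError(f"window [{t_start}, {t_end}) ms selects no samples")
        return EpochSet(self.data[:, :, mask], self.labels, self.subjects, self.fs, float(t[mask][0]))


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32))
        f.create_dataset("labels", data=epochs.labels.astype(np.int8))
        subj = np.asarray([str(s) for s in epochs.subjects], dtype="S")
        f.create_dataset("subjects", data=subj)
        f.attrs["fs"] = epochs.fs
        f.attrs["t0_ms"] = epochs.t0_ms


def read_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        for name in ("data", "labels", "subjects"):
            if name not in f:
                raise ValueError(f"epoch container missing dataset {name!r}")
        data = f["data"][()].astype(np.float64)
        labels = f["labels"][()]
        subjects = np.array([s.decode() for s in f["subjects"][()]])
        fs = float(f.attrs["fs"])
        t0 = float(f.attrs.get("t0_ms", 0.0))
    return EpochSet(data, labels, subjects, fs, t0)


_TRIAL_COLUMNS = ["subject", "cue", "target_position", "rt_ms", "correct"]


@dataclass
class TrialTable:
    """Behavioral trials: one row per target trial following a cue.

    ``cue`` is 'repeat' or 'switch'; ``target_position`` is 1..3 (analysis is
    limited to the first three post-cue targets, where behavioral costs have
    not yet reached asymptote).
    """

    df: pd.DataFrame
    epoch_index: np.ndarray | None = field(default=None)

    def __post_init__(self):
        missing = [c for c in _TRIAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        if not self.df["cue"].isin(["repeat", "switch"]).all():
            raise ValueError("cue must be 'repeat' or 'switch'")
        if not self.df["target_position"].isin([1, 2, 3]).all():
            raise ValueError("target_position must be in {1, 2, 3}")
        if not self.df["correct"].isin([0, 1]).all():
            raise ValueError("correct must be binary")
        bad = (self.df["correct"] == 1) & (self.df["rt_ms"] <= 0)
        if bad.any():
            raise ValueError("correct trials must have positive RT")

    def __len__(self) -> int:
        return len(self.df)


def read_trials(path: str | Path) -> TrialTable:
    return TrialTable(pd.read_csv(path))


def write_trials(trials: TrialTable, path: str | Path) -> None:
    trials.df.to_csv(path, index=False, columns=_TRIAL_COLUMNS)
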