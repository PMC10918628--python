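"""Sequence and dataset representation shared by every other module.

DNA sequences are carried as one-hot arrays of shape (n_sequences, length, 4)
with one channel per nucleotide. The channel order follows the A,C,G,T
convention used throughout regulatory genomics; ambiguous bases (N) are
encoded as a uniform 0.25 vector so each position row keeps unit mass,
which the mutation and noise transforms rely on.

Datasets pair a one-hot batch with a (n_sequences, n_tasks) label array and
can be read from / written to FASTA+TSV or an HDF5 file laid out as
``x_train/y_train/x_valid/y_valid/x_test/y_test`` — the layout popularised
by STARR-seq enhancer-activity regression datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import h5py
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

__all__ = [
    "DNA_ALPHABET",
    "OneHotBatch",
    "LabeledDataset",
    "encode",
    "decode",
    "complement_permutation",
    "read_dataset",
    "write_dataset",
    "read_fasta_tsv",
    "write_fasta_tsv",
    "read_hdf5",
    "write_hdf5",
]


@dataclass
class OneHotBatch:
    """A batch of equal-length one-hot encoded DNA sequences.

    Parameters
    ----------
    data:
        Array of shape ``(n_sequences, length, 4)``. Rows are strictly
        one-hot except where produced by the noise transform or the
        N-ambiguity policy (uniform 0.25).
    alphabet:
        Ordered four-letter DNA alphabet naming the channels.
    """

    data: np.ndarray
    alphabet: str = DNA_ALPHABET

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[2] != 4:
            raise ValueError(
                f"one-hot batch must have shape (n, length, 4); got {self.data.shape}"
            )
        if len(self.alphabet) != 4 or set(self.alphabet) != set(DNA_ALPHABET):
            raise ValueError(f"alphabet must be a permutation of ACGT; got {self.alphabet!r}")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def length(self) -> int:
        """Shared sequence length."""
        return self.data.shape[1]

    def copy(self) -> "OneHotBatch":
        return OneHotBatch(self.data.copy(), self.alphabet)

    def is_strict_onehot(self, atol: float = 1e-9) -> bool:
        """True if every position row has exactly one entry equal to 1."""
        d = self.data
        ones = np.isclose(d, 1.0, atol=atol).sum(axis=2)
        zeros = np.isclose(d, 0.0, atol=atol).sum(axis=2)
        return bool(np.all(ones == 1) and np.all(zeros == 3))


@dataclass
class LabeledDataset:
    """One-hot sequences paired with per-task scalar labels."""

    x: OneHotBatch
    y: np.ndarray
    split_tag: str = "train"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.y.ndim == 1:
            self.y = self.y[:, None]
        if self.y.ndim != 2:
            raise ValueError("labels must be a (n_sequences, n_tasks) array")
        if self.y.shape[0] != len(self.x):
            raise ValueError(
                f"label/sequence count mismatch: {self.y.shape[0]} labels for {len(self.x)} sequences"
            )
        if self.y.shape[1] < 1:
            raise ValueError("n_tasks must be >= 1")
        if self.split_tag not in ("train", "valid", "test"):
            raise ValueError(f"split_tag must be train/valid/test; got {self.split_tag!r}")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def n_tasks(self) -> int:
        return self.y.shape[1]

    def subset(self, indices: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            OneHotBatch(self.x.data[indices], self.x.alphabet),
            self.y[indices],
            self.split_tag,
        )


def encode(sequences: Iterable[str], alphabet: str = DNA_ALPHABET) -> OneHotBatch:
    """One-hot encode equal-length DNA strings (case-insensitive, N allowed).

    N is encoded as a uniform 0.25 row. Unequal lengths or characters
    outside {A,C,G,T,N} raise ``ValueError``.
    """
    seqs = [s.upper() for s in sequences]
    if not seqs:
        return OneHotBatch(np.zeros((0, 0, 4)), alphabet)
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("length mismatch: all sequences in a batch must share one length")
    lut = np.full(128, -1, dtype=np.int8)
    for i, base in enumerate(alphabet):
        lut[ord(base)] = i
    lut[ord("N")] = 4
    codes = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    idx = lut[codes]
    if np.any(idx < 0):
        bad = chr(codes[int(np.argmax(lut[codes] < 0))])
        raise ValueError(f"alphabet error: illegal character {bad!r} (allowed: ACGTN)")
    # row 4 of the basis handles N -> uniform 0.25
    basis = np.vstack([np.eye(4), np.full(4, 0.25)])
    data = basis[idx].reshape(len(seqs), length, 4)
    return OneHotBatch(data, alphabet)


def decode(batch: OneHotBatch) -> list[str]:
    """Decode each position to the letter of its max channel.

    Ties are broken in alphabet order (argmax returns the first maximum),
    so an all-0.25 row decodes to the first alphabet letter.
    """
    letters = np.array(list(batch.alphabet))
    idx = np.argmax(batch.data, axis=2)
    return ["".join(row) for row in letters[idx]]


def complement_permutation(alphabet: str = DNA_ALPHABET) -> np.ndarray:
    """Channel permutation sending each base's channel to its complement's."""
    return np.array([alphabet.index(_COMPLEMENT[b]) for b in alphabet])


# ---------------------------------------------------------------------------
# File I/O


def write_fasta_tsv(dataset: LabeledDataset, fasta_path, tsv_path, ids=None) -> None:
    """Write sequences to FASTA and labels to a TSV (id + one column per task)."""
    seqs = decode(dataset.x)
    if ids is None:
        ids = [f"seq{i}" for i in range(len(seqs))]
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in zip(ids, seqs)]
    SeqIO.write(records, str(fasta_path), "fasta")
    cols = {f"task{t}": dataset.y[:, t] for t in range(dataset.n_tasks)}
    pd.DataFrame({"id": ids, **cols}).to_csv(tsv_path, sep="\t", index=False)


def read_fasta_tsv(fasta_path, tsv_path, split_tag: str = "train") -> LabeledDataset:
    """Read a FASTA of sequences plus a TSV of per-id labels.

    Every TSV id must be present in the FASTA and vice versa; a mismatch
    raises a consistency ``ValueError``.
    """
    records = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta_path), "fasta")}
    table = pd.read_csv(tsv_path, sep="\t")
    tsv_ids = list(table.iloc[:, 0].astype(str))
    missing = [i for i in tsv_ids if i not in records]
    if missing:
        raise ValueError(f"consistency error: label id(s) absent from FASTA: {missing[:3]}")
    extra = [i for i in records if i not in set(tsv_ids)]
    if extra:
        raise ValueError(f"consistency error: FASTA id(s) without labels: {extra[:3]}")
    x = encode([records[i] for i in tsv_ids])
    y = table.iloc[:, 1:].to_numpy(dtype=np.float64)
    return LabeledDataset(x, y, split_tag)


def write_hdf5(splits: Mapping[str, LabeledDataset], path) -> None:
    """Write train/valid/test splits as x_<split>/y_<split> HDF5 arrays."""
    with h5py.File(path, "w") as f:
        for tag, ds in splits.items():
            f.create_dataset(f"x_{tag}", data=ds.x.data)
            f.create_dataset(f"y_{tag}", data=ds.y)
        f.attrs["alphabet"] = next(iter(splits.values())).x.alphabet if splits else DNA_ALPHABET


def read_hdf5(path) -> dict[str, LabeledDataset]:
    """Read every x_<split>/y_<split> pair present in the file."""
    out: dict[str, LabeledDataset] = {}
    with h5py.File(path, "r") as f:
        alphabet = f.attrs.get("alphabet", DNA_ALPHABET)
        if isinstance(alphabet, bytes):
            alphabet = alphabet.decode()
        for tag in ("train", "valid", "test"):
            if f"x_{tag}" in f:
                if f"y_{tag}" not in f:
                    raise ValueError(f"consistency error: x_{tag} present without y_{tag}")
                out[tag] = LabeledDataset(
                    OneHotBatch(f[f"x_{tag}"][:], str(alphabet)), f[f"y_{tag}"][:], tag
                )
    if not out:
        raise ValueError("no x_<split>/y_<split> datasets found in HDF5 file")
    return out


def read_dataset(path, format: str, split_tag: str = "train"):
    """Read a dataset; ``format`` is ``"hdf5"`` or ``"fasta+tsv"``.

    For ``fasta+tsv`` the path is the FASTA file and the TSV is expected
    beside it with a ``.tsv`` suffix. HDF5 returns a dict of splits.
    """
    if format == "hdf5":
        return read_hdf5(path)
    if format == "fasta+tsv":
        p = Path(path)
        return read_fasta_tsv(p, p.with_suffix(".tsv"), split_tag)
    raise ValueError(f"unknown format {format!r}")


def write_dataset(dataset, path, format: str) -> None:
    if format == "hdf5":
        splits = dataset if isinstance(dataset, Mapping) else {dataset.split_tag: dataset}
        write_hdf5(splits, path)
    elif format == "fasta+tsv":
        p = Path(path)
        write_fasta_tsv(dataset, p, p.with_suffix(".tsv"))
    else:
        raise ValueError(f"unknown format {format!r}")
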