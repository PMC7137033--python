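"""Feature encoding of site windows.

A 41-nt window is mapped to 244 named features: a per-position one-hot binary
block (41 x 4 = 164), then the 2-mer spectrum (16), then the 3-mer spectrum
(64).  Lengths other than 41 are supported via the generalized dimension
formula 4*L + 16 + 64.

Feature names are a pure function of (L, descriptor set): the binary block is
named ``b1`` ... ``b{4L}`` (position p contributes ``b{4(p-1)+1}`` ...
``b{4(p-1)+4}``), spectrum features carry the literal k-mer string.  k-mers
are enumerated lexicographically over A < C < G < U.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from rna5hmc.sequence_io import LabeledDataset, SiteWindow

# Per-base 4-bit codes, most significant bit first.
BINARY_CODES: dict[str, tuple[int, int, int, int]] = {
    "A": (0, 0, 0, 1),
    "U": (0, 0, 1, 0),
    "C": (0, 1, 0, 0),
    "G": (1, 0, 0, 0),
}

ALPHABET = "ACGU"

DESCRIPTORS = ("binary", "kmer2", "kmer3")  # fixed concatenation order


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values and names length mismatch")


@dataclass
class FeatureMatrix:
    """samples x named features, with parallel row identifiers."""

    values: np.ndarray  # shape (n_samples, n_features)
    names: tuple[str, ...]
    row_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.names):
            raise ValueError("column count != number of feature names")
        if self.values.shape[0] != len(self.row_ids):
            raise ValueError("row count != number of row ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.row_ids), columns=list(self.names))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="id")
        return cls(
            values=frame.to_numpy(dtype=float),
            names=tuple(frame.columns),
            row_ids=tuple(str(i) for i in frame.index),
        )


def kmer_names(k: int) -> tuple[str, ...]:
    """All 4^k k-mers in lexicographic order over A < C < G < U."""
    return tuple("".join(p) for p in product(ALPHABET, repeat=k))


def binary_names(L: int) -> tuple[str, ...]:
    return tuple(f"b{i}" for i in range(1, 4 * L + 1))


def feature_names(L: int, descriptors: Sequence[str] = DESCRIPTORS) -> tuple[str, ...]:
    """Column names for a (L, descriptor subset) encoding; data-independent."""
    _check_descriptors(descriptors)
    names: list[str] = []
    if "binary" in descriptors:
        names.extend(binary_names(L))
    if "kmer2" in descriptors:
        names.extend(kmer_names(2))
    if "kmer3" in descriptors:
        names.extend(kmer_names(3))
    return tuple(names)


def kmer_spectrum(window: SiteWindow, k: int) -> FeatureVector:
    """Occurrence-frequency vector of all 4^k k-mers of the window.

    Each of the L - k + 1 substring positions contributes 1/(L - k + 1), so
    the spectrum sums to 1.
    """
    seq = window.seq
    L = len(seq)
    if not 1 <= k < L:
        raise ValueError(f"k must satisfy 1 <= k < L, got k={k}, L={L}")
    names = kmer_names(k)
    index = {kmer: i for i, kmer in enumerate(names)}
    counts = np.zeros(len(names))
    for i in range(L - k + 1):
        counts[index[seq[i : i + k]]] += 1
    return FeatureVector(values=counts / (L - k + 1), names=names)


def binary_encoding(window: SiteWindow) -> FeatureVector:
    """Concatenated per-position 4-bit one-hot codes (A=0001, U=0010, C=0100, G=1000)."""
    values = np.fromiter(
        (bit for base in window.seq for bit in BINARY_CODES[base]),
        dtype=float,
        count=4 * len(window.seq),
    )
    return FeatureVector(values=values, names=binary_names(len(window.seq)))


def _check_descriptors(descriptors: Sequence[str]) -> None:
    if not descriptors:
        raise ValueError("at least one descriptor must be selected")
    unknown = set(descriptors) - set(DESCRIPTORS)
    if unknown:
        raise ValueError(f"unknown descriptors: {sorted(unknown)}; valid: {DESCRIPTORS}")


def encode(window: SiteWindow, descriptors: Sequence[str] = DESCRIPTORS) -> FeatureVector:
    """Full feature vector: binary (4L), then 2-mer (16), then 3-mer (64).

    For the default L=41 and all descriptors the dimension is
    41*4 + 4**2 + 4**3 = 244.
    """
    _check_descriptors(descriptors)
    parts: list[np.ndarray] = []
    names: list[str] = []
    if "binary" in descriptors:
        fv = binary_encoding(window)
        parts.append(fv.values)
        names.extend(fv.names)
    if "kmer2" in descriptors:
        fv = kmer_spectrum(window, 2)
        parts.append(fv.values)
        names.extend(fv.names)
    if "kmer3" in descriptors:
        fv = kmer_spectrum(window, 3)
        parts.append(fv.values)
        names.extend(fv.names)
    return FeatureVector(values=np.concatenate(parts), names=tuple(names))


def encode_dataset(
    dataset: LabeledDataset | Iterable[SiteWindow],
    descriptors: Sequence[str] = DESCRIPTORS,
) -> FeatureMatrix:
    """Encode every window of a dataset into a :class:`FeatureMatrix`.

    Columns follow the fixed descriptor order binary, 2-mer, 3-mer restricted
    to the selection, so all seven descriptor combinations are expressible.
    """
    windows = dataset.windows if isinstance(dataset, LabeledDataset) else list(dataset)
    _check_descriptors(descriptors)
    if not windows:
        names = feature_names(0, descriptors)
        return FeatureMatrix(values=np.empty((0, len(names))), names=names, row_ids=())
    rows = [encode(w, descriptors) for w in windows]
    return FeatureMatrix(
        values=np.vstack([r.values for r in rows]),
        names=rows[0].names,
        row_ids=tuple(w.id for w in windows),
    )
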