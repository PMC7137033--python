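"""Reading, validation, and writing of fixed-length RNA site windows.

A *site window* is an odd-length sequence over {A, C, G, U} whose central
position holds the candidate modified cytosine.  Coordinates are 1-based and
inclusive throughout: the center of a 41-nt window is position 21.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_LENGTH = 41
RNA_ALPHABET = frozenset("ACGU")

POSITIVE = 1
NEGATIVE = 0


class FastaFormatError(ValueError):
    """Raised when a file does not parse as FASTA."""


class WindowValidationError(ValueError):
    """Rejection of a raw sequence, with a machine-readable reason.

    ``reason`` is one of ``bad_length``, ``bad_alphabet``, ``bad_center``.
    """

    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


@dataclass(frozen=True)
class SiteWindow:
    """A validated fixed-length RNA window with a centered candidate site."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def center_index(self) -> int:
        """1-based position of the candidate site: (L + 1) / 2."""
        return (len(self.seq) + 1) // 2

    @property
    def center_base(self) -> str:
        return self.seq[self.center_index - 1]


@dataclass
class LabeledDataset:
    """Ordered windows with parallel binary labels (1 = 5hmC, 0 = non-5hmC)."""

    windows: list[SiteWindow]
    labels: list[int]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.windows) != len(self.labels):
            raise ValueError("windows and labels must have equal length")
        ids = [w.id for w in self.windows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate window ids in dataset")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def n_positive(self) -> int:
        return sum(1 for y in self.labels if y == POSITIVE)

    @property
    def n_negative(self) -> int:
        return len(self.labels) - self.n_positive

    def positives(self) -> list[SiteWindow]:
        return [w for w, y in zip(self.windows, self.labels) if y == POSITIVE]

    def negatives(self) -> list[SiteWindow]:
        return [w for w, y in zip(self.windows, self.labels) if y == NEGATIVE]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, sequence)`` pairs in file order.

    Headers are parsed up to the first whitespace; multi-line sequences are
    concatenated and upper-cased.  Sequence data before any ``>`` header is a
    format error.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    with open(path) as handle:
        for line in handle:
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaFormatError(f"{path}: sequence data before any '>' header")
            break
        handle.seek(0)
        try:
            for title, seq in SimpleFastaParser(handle):
                records.append((title.split()[0] if title else "", seq.upper()))
        except ValueError as exc:
            raise FastaFormatError(f"{path}: {exc}") from exc
    return records


def write_fasta(windows: Iterable[SiteWindow], path: str | Path, width: int = 60) -> None:
    """Write windows as FASTA.  Round-trips through :func:`read_fasta`."""
    path = Path(path)
    with open(path, "w") as handle:
        for w in windows:
            handle.write(f">{w.id}\n")
            for i in range(0, len(w.seq), width):
                handle.write(w.seq[i : i + width] + "\n")


def normalize_and_validate(
    id: str,
    raw: str,
    L: int = DEFAULT_WINDOW_LENGTH,
    require_center_c: bool = True,
) -> SiteWindow:
    """Normalize a raw sequence and validate it as a :class:`SiteWindow`.

    ``T``/``t`` is mapped to ``U`` (DNA-alphabet inputs are common for
    immunoprecipitation-derived data); input is upper-cased.  Rejections raise
    :class:`WindowValidationError` with reason ``bad_length`` (length != L),
    ``bad_alphabet`` (any residual character outside {A,C,G,U}; ambiguity
    codes such as N are rejected, not imputed), or ``bad_center``
    (center base != C while ``require_center_c``).
    """
    if not raw:
        raise WindowValidationError("bad_length", f"{id}: empty sequence")
    seq = raw.upper().replace("T", "U")
    if len(seq) != L:
        raise WindowValidationError(
            "bad_length", f"{id}: length {len(seq)} != expected {L}"
        )
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise WindowValidationError(
            "bad_alphabet", f"{id}: characters outside ACGU: {sorted(bad)}"
        )
    center = (L + 1) // 2
    if require_center_c and seq[center - 1] != "C":
        raise WindowValidationError(
            "bad_center", f"{id}: center base {seq[center - 1]!r} at position {center} != C"
        )
    return SiteWindow(id=id, seq=seq)


def _validate_records(
    records: Sequence[tuple[str, str]],
    L: int,
    require_center_c: bool,
    strict: bool,
    source: str,
) -> tuple[list[SiteWindow], int]:
    windows: list[SiteWindow] = []
    dropped = 0
    for rec_id, raw in records:
        try:
            windows.append(normalize_and_validate(rec_id, raw, L, require_center_c))
        except WindowValidationError as exc:
            if strict:
                raise
            dropped += 1
            logger.debug("%s: dropped %s (%s)", source, rec_id, exc.reason)
    if dropped:
        logger.warning("%s: dropped %d invalid record(s)", source, dropped)
    return windows, dropped


def load_labeled(
    pos_path: str | Path,
    neg_path: str | Path,
    L: int = DEFAULT_WINDOW_LENGTH,
    require_center_c: bool = True,
    strict: bool = False,
) -> LabeledDataset:
    """Load a labeled dataset from a positives FASTA and a negatives FASTA.

    Invalid records are dropped with a logged count, or abort the run under
    ``strict``.  A duplicate id across the two files is an error under
    ``strict`` and is disambiguated with a numeric suffix otherwise.  Either
    class ending up empty is an error.
    """
    pos_windows, _ = _validate_records(
        read_fasta(pos_path), L, require_center_c, strict, str(pos_path)
    )
    neg_windows, _ = _validate_records(
        read_fasta(neg_path), L, require_center_c, strict, str(neg_path)
    )
    if not pos_windows:
        raise ValueError(f"{pos_path}: no valid positive records")
    if not neg_windows:
        raise ValueError(f"{neg_path}: no valid negative records")

    seen: dict[str, int] = {}
    windows: list[SiteWindow] = []
    for w in pos_windows + neg_windows:
        if w.id in seen:
            if strict:
                raise ValueError(f"duplicate id across files: {w.id}")
            seen[w.id] += 1
            w = SiteWindow(id=f"{w.id}#{seen[w.id]}", seq=w.seq)
        else:
            seen[w.id] = 1
        windows.append(w)

    labels = [POSITIVE] * len(pos_windows) + [NEGATIVE] * len(neg_windows)
    return LabeledDataset(
        windows=windows,
        labels=labels,
        provenance=f"pos={pos_path} neg={neg_path}",
    )


def load_with_label_table(
    fasta_path: str | Path,
    table_path: str | Path,
    L: int = DEFAULT_WINDOW_LENGTH,
    require_center_c: bool = True,
    strict: bool = False,
) -> LabeledDataset:
    """Load a labeled dataset from one FASTA plus a two-column TSV (id, 0/1)."""
    labels_by_id: dict[str, int] = {}
    with open(table_path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or fields[1] not in {"0", "1"}:
                raise ValueError(f"{table_path}: bad label row {line!r}")
            labels_by_id[fields[0]] = int(fields[1])

    records = read_fasta(fasta_path)
    windows, _ = _validate_records(records, L, require_center_c, strict, str(fasta_path))
    kept: list[SiteWindow] = []
    labels: list[int] = []
    for w in windows:
        if w.id not in labels_by_id:
            if strict:
                raise ValueError(f"{fasta_path}: no label for id {w.id}")
            logger.warning("no label for id %s; dropped", w.id)
            continue
        kept.append(w)
        labels.append(labels_by_id[w.id])
    if POSITIVE not in labels or NEGATIVE not in labels:
        raise ValueError("label table yields an empty class")
    return LabeledDataset(windows=kept, labels=labels, provenance=f"fasta={fasta_path} labels={table_path}")
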