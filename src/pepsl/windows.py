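"""Proteome input and sliding-window decomposition into short polypeptides.

A proteome is read from FASTA and each protein is chopped into overlapping
fixed-length peptide windows (default length ``L=25``, step ``w=5``).  These
windows are the atomic unit of everything downstream: local alignment,
significance filtering, clustering and finally interaction prediction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "PeptideWindow",
    "WindowCatalog",
    "read_fasta",
    "write_fasta",
    "chop_protein",
    "chop_proteome",
]

#: default window length in residues
DEFAULT_L = 25
#: default step of the moving window in residues
DEFAULT_W = 5


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a stable identifier."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.protein_id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideWindow:
    """A fixed-length subsequence of a protein with provenance coordinates.

    Coordinates are 0-based, half-open: the window covers
    ``protein[start : start + length]``.
    """

    protein_id: str
    start: int
    length: int
    sequence: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("window start must be >= 0")
        if len(self.sequence) != self.length:
            raise ValueError(
                f"window {self.protein_id}:{self.start}: sequence length "
                f"{len(self.sequence)} != declared length {self.length}"
            )

    @property
    def key(self) -> tuple[str, int]:
        """Unique identity of a window within a proteome."""
        return (self.protein_id, self.start)

    @property
    def label(self) -> str:
        return f"{self.protein_id}:{self.start}"


class WindowCatalog:
    """Ordered collection of peptide windows with a per-protein index."""

    def __init__(self, windows: Iterable[PeptideWindow]):
        self.windows: list[PeptideWindow] = list(windows)
        self.index: dict[str, list[PeptideWindow]] = {}
        seen: set[tuple[str, int]] = set()
        for w in self.windows:
            if w.key in seen:
                raise ValueError(f"duplicate window {w.label}")
            seen.add(w.key)
            self.index.setdefault(w.protein_id, []).append(w)

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[PeptideWindow]:
        return iter(self.windows)

    def __getitem__(self, i: int) -> PeptideWindow:
        return self.windows[i]

    @property
    def protein_ids(self) -> list[str]:
        return list(self.index)

    def by_protein(self, protein_id: str) -> list[PeptideWindow]:
        return list(self.index.get(protein_id, []))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": [w.protein_id for w in self.windows],
                "start": [w.start for w in self.windows],
                "length": [w.length for w in self.windows],
                "sequence": [w.sequence for w in self.windows],
            }
        )

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "WindowCatalog":
        df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "sequence": str})
        return cls(
            PeptideWindow(row.protein_id, int(row.start), int(row.length), row.sequence)
            for row in df.itertuples(index=False)
        )


def read_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    """Read a proteome FASTA file into a list of :class:`ProteinRecord`.

    The identifier is the first whitespace-delimited token of the header and
    sequences are uppercased.  Duplicate identifiers and empty files raise
    ``ValueError``.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ValueError(f"duplicate protein identifier {pid!r} in {path}")
        seen.add(pid)
        records.append(ProteinRecord(pid, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | os.PathLike) -> None:
    """Write protein records to FASTA (60-column wrapped)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def chop_protein(
    record: ProteinRecord, L: int = DEFAULT_L, w: int = DEFAULT_W
) -> list[PeptideWindow]:
    """Decompose one protein into overlapping windows of length ``L``, step ``w``.

    For a protein of length ``n >= L`` the windows start at ``0, w, 2w, ...``
    while ``start + L <= n``, giving ``floor((n - L) / w) + 1`` windows.
    Proteins shorter than ``L`` yield a single window spanning the whole
    sequence, so even the shortest proteins stay in the catalog.  Trailing
    residues not covered by the last full window get no extra tail window.
    """
    if L < 1 or w < 1:
        raise ValueError("L and w must be >= 1")
    n = len(record)
    if n < L:
        return [PeptideWindow(record.protein_id, 0, n, record.sequence)]
    return [
        PeptideWindow(record.protein_id, s, L, record.sequence[s : s + L])
        for s in range(0, n - L + 1, w)
    ]


def chop_proteome(
    records: Sequence[ProteinRecord], L: int = DEFAULT_L, w: int = DEFAULT_W
) -> WindowCatalog:
    """Chop every protein and assemble a :class:`WindowCatalog`.

    Ordering is deterministic: input protein order, then window start.
    """
    out: list[PeptideWindow] = []
    for rec in records:
        out.extend(chop_protein(rec, L, w))
    return WindowCatalog(out)
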