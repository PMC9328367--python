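"""Rectangular character matrices with transcriptome-style missing data.

The container is deliberately small: an ordered list of labels plus a numpy
byte matrix.  Missing data is the set {-, N, ?} (case-insensitive), matching
character-occupancy accounting in phylotranscriptomic supermatrices.
FASTA I/O goes through Biopython.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING_CHARS = frozenset(b"-N?")

__all__ = ["Alignment", "MISSING_CHARS"]


@dataclass
class Alignment:
    """Labels + (n_rows, n_cols) matrix of single-byte characters."""

    labels: list[str]
    data: np.ndarray  # dtype '|S1', shape (n, L)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype="S1")
        if self.data.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label count does not match row count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in alignment")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_pairs(cls, pairs) -> "Alignment":
        labels, seqs = [], []
        for label, seq in pairs:
            labels.append(label)
            seqs.append(seq.upper())
        if seqs and len({len(s) for s in seqs}) > 1:
            raise ValueError("alignment rows differ in length")
        n = len(seqs)
        L = len(seqs[0]) if seqs else 0
        data = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(n, L) if n else np.empty((0, 0), "S1")
        return cls(labels, data.copy())

    @classmethod
    def read_fasta(cls, path_or_handle) -> "Alignment":
        records = SeqIO.parse(path_or_handle, "fasta")
        return cls.from_pairs((r.id, str(r.seq)) for r in records)

    @classmethod
    def from_fasta_str(cls, text: str) -> "Alignment":
        return cls.read_fasta(io.StringIO(text))

    # -- basic views -------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    def row(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]

    def sequence(self, label: str) -> str:
        return self.row(label).tobytes().decode()

    def missing_mask(self) -> np.ndarray:
        """Boolean mask of missing cells ({-, N, ?})."""
        m = np.zeros(self.data.shape, dtype=bool)
        for ch in MISSING_CHARS:
            m |= self.data == bytes([ch])
        return m

    def unambiguous_counts(self) -> dict[str, int]:
        """Per-row count of non-missing characters."""
        nonmiss = ~self.missing_mask()
        return {lab: int(c) for lab, c in zip(self.labels, nonmiss.sum(axis=1))}

    def occupancy(self) -> float:
        """Fraction of non-missing cells (1.0 for an empty matrix)."""
        if self.data.size == 0:
            return 1.0
        return 1.0 - self.missing_mask().mean()

    # -- edits -------------------------------------------------------------
    def take_columns(self, idx) -> "Alignment":
        return Alignment(list(self.labels), self.data[:, idx])

    def subset(self, labels) -> "Alignment":
        rows = [self.labels.index(l) for l in labels]
        return Alignment(list(labels), self.data[rows])

    def drop_rows(self, labels) -> "Alignment":
        drop = set(labels)
        keep = [i for i, l in enumerate(self.labels) if l not in drop]
        return Alignment([self.labels[i] for i in keep], self.data[keep])

    # -- output ------------------------------------------------------------
    def to_fasta(self, handle_or_path) -> None:
        recs = [
            SeqRecord(Seq(self.data[i].tobytes().decode()), id=lab, description="")
            for i, lab in enumerate(self.labels)
        ]
        SeqIO.write(recs, handle_or_path, "fasta")

    def to_fasta_str(self) -> str:
        buf = io.StringIO()
        self.to_fasta(buf)
        return buf.getvalue()

    def to_phylip(self, handle) -> None:
        """Relaxed PHYLIP (label, space, sequence on one line)."""
        close = False
        if isinstance(handle, str):
            handle = open(handle, "w")
            close = True
        try:
            handle.write(f"{self.n_rows} {self.n_cols}\n")
            for i, lab in enumerate(self.labels):
                handle.write(f"{lab}  {self.data[i].tobytes().decode()}\n")
        finally:
            if close:
                handle.close()
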