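"""Genome assembly container: named scaffolds with optional soft-masking.

The assembly is the coordinate substrate for every downstream stage. Sequences
are held as plain Python strings; lowercase bases mark repeat-masked
(soft-masked) positions, ``N`` marks unknown bases. FASTA I/O goes through
Biopython and preserves case.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _seq


@dataclass
class Assembly:
    """An ordered collection of named scaffold sequences.

    Parameters
    ----------
    sequences
        Mapping of scaffold name to sequence string (case preserved).
    """

    sequences: dict[str, str] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def length(self, name: str) -> int:
        return len(self.sequences[name])

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def codes(self, name: str) -> np.ndarray:
        """2-bit codes of a scaffold, case-insensitive (masking ignored)."""
        return _seq.encode(self.sequences[name])

    def mask(self, name: str) -> np.ndarray:
        """Boolean soft-mask track of a scaffold (True = lowercase)."""
        return _seq.mask_of(self.sequences[name])

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "Assembly":
        seqs = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            seqs[rec.id] = str(rec.seq)
        if not seqs:
            raise ValueError(f"no sequences found in {path}")
        return cls(seqs)

    def to_fasta(self, path: str | os.PathLike, width: int = 60) -> None:
        records = (
            SeqRecord(Seq(s), id=n, description="") for n, s in self.sequences.items()
        )
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(records)
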