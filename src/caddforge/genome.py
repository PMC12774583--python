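"""Reference-genome access.

A genome is held in memory as uppercase per-chromosome strings. Toy and
chromosome-scale references both fit comfortably; random access is by
1-based inclusive coordinates, matching the rest of the package.
"""

from __future__ import annotations

import os
from collections.abc import Iterator, Mapping

from pyfaidx import Fasta

VALID_BASES = frozenset("ACGT")


class Genome(Mapping[str, str]):
    """Uppercase in-memory reference sequences keyed by chromosome name."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: str(seq).upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "Genome":
        with Fasta(str(path)) as fa:
            return cls({name: str(fa[name][:]) for name in fa.keys()})

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def base(self, chrom: str, pos: int) -> str:
        """Base at 1-based position ``pos``."""
        return self._seqs[chrom][pos - 1]

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Subsequence for the 1-based inclusive interval [start, end]."""
        return self._seqs[chrom][start - 1 : end]

    def to_fasta(self, path: str | os.PathLike, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
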