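"""MAF (multiple alignment format) reading and writing.

Blocks start with an ``a`` line and contain ``s`` rows::

    s <src> <start> <size> <strand> <srcSize> <text>

Coordinates are 0-based half-open in the coordinate system of the named
strand: for a ``-`` row, ``start`` counts from the 3' end of the forward
source and the forward-strand start is ``srcSize - start - size``.
``e``/``i``/``q`` lines are ignored; sequence text is uppercased on input.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from typing import Iterable, Iterator, TextIO

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving gap characters."""
    return seq.translate(_COMPLEMENT)[::-1]


class MafParseError(ValueError):
    pass


@dataclass(frozen=True)
class MafRow:
    src: str          # "species.chrom" (or bare species)
    start: int        # 0-based, on the named strand
    size: int         # ungapped length
    strand: str       # '+' or '-'
    src_size: int
    text: str         # gapped, uppercase

    @property
    def species(self) -> str:
        return self.src.split(".", 1)[0]

    @property
    def chrom(self) -> str:
        parts = self.src.split(".", 1)
        return parts[1] if len(parts) == 2 else parts[0]

    @property
    def forward_start(self) -> int:
        """0-based start on the forward strand of the source sequence."""
        if self.strand == "+":
            return self.start
        return self.src_size - self.start - self.size


@dataclass(frozen=True)
class AlignmentBlock:
    rows: tuple[MafRow, ...]

    def __post_init__(self):
        widths = {len(r.text) for r in self.rows}
        if len(widths) > 1:
            raise MafParseError(f"rows of unequal gapped length: {sorted(widths)}")

    def row_for_species(self, species: str) -> MafRow | None:
        for row in self.rows:
            if row.species == species:
                return row
        return None


def parse_maf(source: str | os.PathLike | TextIO) -> Iterator[AlignmentBlock]:
    """Yield alignment blocks from a MAF file or open text stream."""
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            yield from _parse_stream(fh)
    else:
        yield from _parse_stream(source)


def _parse_stream(fh: TextIO) -> Iterator[AlignmentBlock]:
    rows: list[MafRow] = []
    in_block = False
    for lineno, raw in enumerate(fh, start=1):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            if not stripped and in_block and rows:
                yield AlignmentBlock(tuple(rows))
                rows, in_block = [], False
            continue
        tag = stripped.split(None, 1)[0]
        if tag == "a":
            if in_block and rows:
                yield AlignmentBlock(tuple(rows))
                rows = []
            in_block = True
        elif tag == "s":
            if not in_block:
                raise MafParseError(f"line {lineno}: 's' line outside an 'a' block")
            rows.append(_parse_s_line(stripped, lineno))
        elif tag in ("e", "i", "q"):
            continue
        else:
            raise MafParseError(f"line {lineno}: unrecognized line type {tag!r}")
    if in_block and rows:
        yield AlignmentBlock(tuple(rows))


def _parse_s_line(line: str, lineno: int) -> MafRow:
    fields = line.split()
    if len(fields) != 7:
        raise MafParseError(
            f"line {lineno}: 's' line has {len(fields)} fields, expected 7"
        )
    _, src, start, size, strand, src_size, text = fields
    try:
        start_i, size_i, src_size_i = int(start), int(size), int(src_size)
    except ValueError as exc:
        raise MafParseError(f"line {lineno}: non-integer coordinate field") from exc
    if strand not in ("+", "-"):
        raise MafParseError(f"line {lineno}: bad strand {strand!r}")
    text = text.upper()
    ungapped = sum(1 for c in text if c != "-")
    if ungapped != size_i:
        raise MafParseError(
            f"line {lineno}: size {size_i} != non-gap character count {ungapped}"
        )
    if start_i < 0 or start_i + size_i > src_size_i:
        raise MafParseError(f"line {lineno}: coordinates exceed srcSize")
    return MafRow(src, start_i, size_i, strand, src_size_i, text)


def write_maf(blocks: Iterable[AlignmentBlock], dest: str | os.PathLike | TextIO) -> None:
    """Serialize blocks in standard MAF layout (whitespace-normalized)."""
    own = isinstance(dest, (str, os.PathLike))
    fh: TextIO = open(dest, "w") if own else dest  # type: ignore[assignment]
    try:
        fh.write("##maf version=1\n")
        for block in blocks:
            fh.write("\na\n")
            for r in block.rows:
                fh.write(
                    f"s {r.src} {r.start} {r.size} {r.strand} {r.src_size} {r.text}\n"
                )
    finally:
        if own:
            fh.close()


def maf_to_string(blocks: Iterable[AlignmentBlock]) -> str:
    buf = io.StringIO()
    write_maf(blocks, buf)
    return buf.getvalue()
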