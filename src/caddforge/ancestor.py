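"""Projection of an inferred ancestral sequence onto reference coordinates.

The ancestral genome is read off a multiple alignment either from an
explicit ancestor row (as Progressive Cactus emits) or by consensus over a
set of outgroup rows (for Compara-style exports without ancestor rows).
Every reference position gets exactly one of: a concrete ancestral base,
UNALIGNED (no block covers it, or the ancestor carries a gap/N there), or
AMBIGUOUS (overlapping blocks disagree). Only concrete positions enter the
variant sets downstream.
"""

from __future__ import annotations

import os
from collections import Counter
from typing import Iterable, Literal

import numpy as np

from .genome import Genome
from .maf import AlignmentBlock, MafRow

UNALIGNED = "."
AMBIGUOUS = "?"

_U = ord(UNALIGNED)
_A = ord(AMBIGUOUS)
_BASES = frozenset(b"ACGT")
_COMP = np.zeros(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTN-", b"TGCAN-"):
    _COMP[_x] = _y


class AncestorMapError(ValueError):
    pass


class AncestorMap:
    """Per-chromosome array of ancestral alleles in 1-based reference coordinates."""

    def __init__(self, chrom_lengths: dict[str, int]):
        self._arr = {
            c: np.full(n, _U, dtype=np.uint8) for c, n in chrom_lengths.items()
        }

    @property
    def chroms(self) -> list[str]:
        return list(self._arr)

    def array(self, chrom: str) -> np.ndarray:
        """Raw uint8 array of allele characters (index 0 = position 1)."""
        return self._arr[chrom]

    def get(self, chrom: str, pos: int) -> str:
        return chr(self._arr[chrom][pos - 1])

    def set(self, chrom: str, pos: int, allele: str) -> None:
        self._arr[chrom][pos - 1] = ord(allele)

    def concrete_mask(self, chrom: str) -> np.ndarray:
        a = self._arr[chrom]
        return (a != _U) & (a != _A)

    def length(self, chrom: str) -> int:
        return len(self._arr[chrom])

    # -- serialization ----------------------------------------------------

    def to_tsv(self, path: str | os.PathLike) -> None:
        """Write non-UNALIGNED positions as chrom<TAB>pos<TAB>allele."""
        with open(path, "w") as fh:
            fh.write("#chrom\tpos\tallele\n")
            for chrom, arr in self._arr.items():
                idx = np.nonzero(arr != _U)[0]
                alleles = arr[idx]
                for i, al in zip(idx, alleles):
                    fh.write(f"{chrom}\t{i + 1}\t{chr(al)}\n")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, chrom_lengths: dict[str, int]) -> "AncestorMap":
        amap = cls(chrom_lengths)
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                try:
                    chrom, pos, allele = line.rstrip("\n").split("\t")
                    amap.set(chrom, int(pos), allele)
                except (ValueError, KeyError, IndexError) as exc:
                    raise AncestorMapError(f"{path}: bad record at line {lineno}") from exc
        return amap

    def to_fasta_like(self, path: str | os.PathLike, width: int = 60) -> None:
        """Ancestral sequence with '.' for unaligned and '?' for ambiguous sites."""
        with open(path, "w") as fh:
            for chrom, arr in self._arr.items():
                fh.write(f">{chrom}\n")
                s = arr.tobytes().decode("ascii")
                for i in range(0, len(s), width):
                    fh.write(s[i : i + width] + "\n")


def _column_positions(ref_row: MafRow) -> tuple[np.ndarray, np.ndarray]:
    """0-based forward reference positions of each non-gap reference column.

    Returns (column indices into the gapped text, forward positions).
    """
    text = np.frombuffer(ref_row.text.encode("ascii"), dtype=np.uint8)
    cols = np.nonzero(text != ord("-"))[0]
    offsets = np.arange(len(cols))
    if ref_row.strand == "+":
        pos0 = ref_row.forward_start + offsets
    else:
        # text reads along the reverse strand: forward positions descend
        pos0 = (ref_row.forward_start + ref_row.size - 1) - offsets
    return cols, pos0


def _ancestor_column(
    block: AlignmentBlock,
    ancestor_label: str | None,
    outgroup_labels: list[str] | None,
    strategy: str,
) -> np.ndarray | None:
    """Per-column ancestral character array (uint8), or None if unavailable."""
    if ancestor_label is not None:
        row = block.row_for_species(ancestor_label)
        if row is None:
            return None
        return np.frombuffer(row.text.encode("ascii"), dtype=np.uint8).copy()

    rows = [block.row_for_species(lbl) for lbl in outgroup_labels or []]
    rows = [r for r in rows if r is not None]
    if not rows:
        return None
    texts = np.stack(
        [np.frombuffer(r.text.encode("ascii"), dtype=np.uint8) for r in rows]
    )
    width = texts.shape[1]
    out = np.full(width, ord("-"), dtype=np.uint8)
    if strategy == "strict_consensus":
        first = texts[0]
        agree = np.all(texts == first, axis=0)
        valid = np.isin(first, list(_BASES))
        out[agree & valid] = first[agree & valid]
    elif strategy == "majority":
        for j in range(width):
            counts = Counter(
                int(c) for c in texts[:, j] if int(c) in (65, 67, 71, 84)
            )
            if not counts:
                continue
            ranked = counts.most_common()
            if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
                out[j] = _A
            else:
                out[j] = ranked[0][0]
    else:
        raise AncestorMapError(f"unknown consensus strategy {strategy!r}")
    return out


def build_ancestor_map(
    blocks: Iterable[AlignmentBlock],
    genome: Genome,
    ref_species: str,
    ancestor_label: str | None = None,
    outgroup_labels: list[str] | None = None,
    strategy: Literal["strict_consensus", "majority"] = "strict_consensus",
) -> AncestorMap:
    """Project ancestral alleles onto forward reference coordinates.

    Exactly one of ``ancestor_label`` / ``outgroup_labels`` must be given.
    Minus-strand reference rows are reverse-complemented into forward
    coordinates. Positions assigned conflicting values by overlapping
    blocks become AMBIGUOUS; gaps and non-ACGT ancestor characters mean
    the site is treated as unaligned.
    """
    if (ancestor_label is None) == (outgroup_labels is None):
        raise AncestorMapError(
            "specify exactly one of ancestor_label or outgroup_labels"
        )

    amap = AncestorMap({c: genome.length(c) for c in genome})
    assigned = {c: np.zeros(genome.length(c), dtype=bool) for c in genome}
    saw_ref = False
    saw_anc = False

    for block in blocks:
        ref_row = block.row_for_species(ref_species)
        if ref_row is None:
            continue
        saw_ref = True
        chrom = ref_row.chrom
        if chrom not in amap._arr:
            raise AncestorMapError(
                f"alignment names chromosome {chrom!r} absent from the reference"
            )
        anc_text = _ancestor_column(block, ancestor_label, outgroup_labels, strategy)
        if anc_text is None:
            continue
        saw_anc = True

        cols, pos0 = _column_positions(ref_row)
        anc = anc_text[cols]
        if ref_row.strand == "-":
            anc = np.where(anc == _A, anc, _COMP[anc])
        # non-ACGT ancestor characters (gap, N, unresolved consensus) -> unaligned
        is_base = np.isin(anc, list(_BASES))
        values = np.where(is_base | (anc == _A), anc, _U).astype(np.uint8)

        arr = amap.array(chrom)
        seen = assigned[chrom]
        prev = arr[pos0]
        fresh = ~seen[pos0]
        conflict = seen[pos0] & (prev != values)
        new = np.where(conflict, _A, np.where(fresh, values, prev))
        arr[pos0] = new
        seen[pos0] = True

    if not saw_ref:
        raise AncestorMapError(f"reference species {ref_species!r} found in no block")
    if not saw_anc:
        who = ancestor_label if ancestor_label is not None else outgroup_labels
        raise AncestorMapError(f"ancestor source {who!r} found in no block")
    return amap


def coverage_stats(amap: AncestorMap, genome: Genome) -> dict[str, float]:
    """Fraction of positions with a concrete ancestral base, per chromosome
    plus a genome-wide ``total``."""
    for chrom in amap.chroms:
        if chrom not in genome:
            raise AncestorMapError(f"chromosome {chrom!r} absent from the genome")
    out: dict[str, float] = {}
    covered_total = 0
    for chrom in amap.chroms:
        n = genome.length(chrom)
        covered = int(amap.concrete_mask(chrom).sum())
        out[chrom] = covered / n if n else 0.0
        covered_total += covered
    total_len = genome.total_length()
    out["total"] = covered_total / total_len if total_len else 0.0
    return out
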