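"""Proxy-neutral (derived) variant calling and SNV containers.

Derived variants are (nearly) fixed alleles separating the reference genome
from the inferred ancestral sequence: at every aligned position where the
ancestral base differs from the reference base, an ancestral->reference
substitution is emitted, provided the reference (derived) allele is fixed or
nearly fixed in the population (allele frequency above ``af_fixed``,
default 0.9). Positions absent from the population VCF are treated as fixed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pysam

from .ancestor import AncestorMap
from .genome import VALID_BASES, Genome

_BASE_CODES = {ord(b): b for b in "ACGT"}


class VariantError(ValueError):
    pass


@dataclass(frozen=True)
class SNV:
    """A single-nucleotide substitution with its training-class label."""

    chrom: str
    pos: int                    # 1-based
    from_allele: str
    to_allele: str
    class_label: str            # 'derived' or 'simulated'
    af: float | None = None     # population AF of to_allele, if known

    def __post_init__(self):
        if self.from_allele == self.to_allele:
            raise VariantError(f"degenerate substitution at {self.chrom}:{self.pos}")
        if self.from_allele not in VALID_BASES or self.to_allele not in VALID_BASES:
            raise VariantError(f"non-ACGT allele at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity used for collision checks: (chrom, pos, substituted-in allele)."""
        return (self.chrom, self.pos, self.to_allele)


@dataclass
class PopulationAF:
    """Per-(chrom, pos, alt) population allele frequencies from a VCF.

    ``alt_sum`` caches the summed alternate-allele frequency per position so
    the reference-allele frequency is ``1 - alt_sum``.
    """

    af: dict[tuple[str, int, str], float] = field(default_factory=dict)
    alt_sum: dict[tuple[str, int], float] = field(default_factory=dict)

    def add(self, chrom: str, pos: int, alt: str, value: float) -> None:
        if not 0.0 <= value <= 1.0:
            raise VariantError(f"AF {value} outside [0,1] at {chrom}:{pos}")
        key = (chrom, pos, alt)
        if key in self.af:
            raise VariantError(f"duplicate AF record for {chrom}:{pos} {alt}")
        self.af[key] = value
        self.alt_sum[(chrom, pos)] = self.alt_sum.get((chrom, pos), 0.0) + value

    def reference_af(self, chrom: str, pos: int) -> float | None:
        """1 - sum of alternate AFs, or None when the position is not listed."""
        s = self.alt_sum.get((chrom, pos))
        return None if s is None else max(0.0, 1.0 - s)

    def get(self, chrom: str, pos: int, alt: str) -> float | None:
        return self.af.get((chrom, pos, alt))

    def __len__(self) -> int:
        return len(self.af)


def load_population_vcf(path: str | os.PathLike) -> PopulationAF:
    """Read alternate-allele frequencies from INFO/AF, falling back to AC/AN.

    Multiallelic records are decomposed per alternate allele; non-SNV
    alternates are skipped.
    """
    pop = PopulationAF()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            alts = rec.alts or ()
            afs = rec.info.get("AF")
            if afs is None:
                ac, an = rec.info.get("AC"), rec.info.get("AN")
                if ac is None or not an:
                    continue
                if not isinstance(ac, (tuple, list)):
                    ac = (ac,)
                afs = tuple(a / an for a in ac)
            elif not isinstance(afs, (tuple, list)):
                afs = (afs,)
            for alt, af in zip(alts, afs):
                if alt is None or len(alt) != 1 or alt.upper() not in VALID_BASES:
                    continue
                if rec.ref is None or len(rec.ref) != 1:
                    continue
                pop.add(rec.chrom, rec.pos, alt.upper(), float(af))
    return pop


def call_derived_variants(
    genome: Genome,
    anc: AncestorMap,
    pop: PopulationAF | None = None,
    af_fixed: float = 0.9,
) -> list[SNV]:
    """Emit one derived SNV per ancestor/reference mismatch at aligned sites.

    The derived allele is the reference base; when the position is listed in
    the population VCF it is kept only if the reference-allele frequency
    (1 - sum of alternate AFs) exceeds ``af_fixed``.
    """
    if not 0.0 < af_fixed <= 1.0:
        raise VariantError(f"af_fixed must lie in (0, 1], got {af_fixed}")
    out: list[SNV] = []
    for chrom in anc.chroms:
        arr = anc.array(chrom)
        ref = np.frombuffer(genome[chrom].encode("ascii"), dtype=np.uint8)
        concrete = anc.concrete_mask(chrom)
        ref_ok = np.isin(ref, [65, 67, 71, 84])
        diff = concrete & ref_ok & (arr != ref)
        for idx in np.nonzero(diff)[0]:
            pos = int(idx) + 1
            ref_af = pop.reference_af(chrom, pos) if pop is not None else None
            if ref_af is not None and ref_af <= af_fixed:
                continue
            out.append(
                SNV(
                    chrom=chrom,
                    pos=pos,
                    from_allele=_BASE_CODES[int(arr[idx])],
                    to_allele=_BASE_CODES[int(ref[idx])],
                    class_label="derived",
                    af=ref_af if ref_af is not None else 1.0,
                )
            )
    return out


# -- serialization --------------------------------------------------------

_TSV_HEADER = "#chrom\tpos\tfrom\tto\tclass\taf\n"


def write_snv_tsv(snvs: list[SNV], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER)
        for v in snvs:
            af = "" if v.af is None else f"{v.af:.6g}"
            fh.write(f"{v.chrom}\t{v.pos}\t{v.from_allele}\t{v.to_allele}\t{v.class_label}\t{af}\n")


def read_snv_tsv(path: str | os.PathLike) -> list[SNV]:
    out: list[SNV] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 6:
                raise VariantError(f"{path}: line {lineno}: expected 6 fields")
            chrom, pos, frm, to, cls, af = fields
            out.append(
                SNV(chrom, int(pos), frm, to, cls, float(af) if af else None)
            )
    return out


def write_snv_vcf(snvs: list[SNV], genome: Genome, path: str | os.PathLike) -> None:
    """VCF export; only records whose from-allele matches the reference base
    are representable (derived variants carry the ancestral base as 'from',
    which usually differs from REF) — others are skipped with a count in the
    header. The TSV is the authoritative serialization."""
    skipped = sum(
        1 for v in snvs if genome.base(v.chrom, v.pos) != v.from_allele
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CLS,Number=1,Type=String,Description="Training class">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Allele frequency">\n')
        fh.write(f"##caddforge_skipped_nonref_from={skipped}\n")
        for chrom in genome:
            fh.write(f"##contig=<ID={chrom},length={genome.length(chrom)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in snvs:
            if genome.base(v.chrom, v.pos) != v.from_allele:
                continue
            info = f"CLS={v.class_label}"
            if v.af is not None:
                info += f";AF={v.af:.6g}"
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.from_allele}\t{v.to_allele}\t.\t.\t{info}\n")
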