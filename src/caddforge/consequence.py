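"""Minimal built-in variant-consequence calling from GFF3 gene models.

Classifies each SNV into one of seven categories (most severe across
overlapping transcripts): stop_gained > missense > splice_site >
synonymous > exonic > intronic > intergenic. ``splice_site`` means within
2 bp of an exon boundary on the intron side. This intentionally covers only
the basic gene-model consequences needed for self-contained runs; rich
consequence sets from an external annotator can be supplied as a
per-variant TSV track instead.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import gffutils
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .genome import Genome
from .maf import revcomp

CONSEQUENCE_LEVELS = (
    "intergenic",
    "intronic",
    "splice_site",
    "exonic",
    "synonymous",
    "missense",
    "stop_gained",
)
_SEVERITY = {name: i for i, name in enumerate(CONSEQUENCE_LEVELS)}
SPLICE_REGION = 2  # bp into the intron counted as splice site


@dataclass
class Transcript:
    chrom: str
    start: int                      # 1-based inclusive
    end: int
    strand: str
    exons: list[tuple[int, int]]    # sorted 1-based inclusive
    cds: list[tuple[int, int]]      # sorted 1-based inclusive


@dataclass(frozen=True)
class Consequence:
    category: str
    aa_ref: str | None = None
    aa_alt: str | None = None


class GeneModels:
    """Transcript structures indexed for point queries."""

    def __init__(self, transcripts: list[Transcript]):
        self.transcripts = transcripts
        self._trees: dict[str, IntervalTree] = {}
        for t in transcripts:
            tree = self._trees.setdefault(t.chrom, IntervalTree())
            tree.addi(t.start, t.end + 1, t)

    @classmethod
    def from_gff3(cls, path: str | os.PathLike) -> "GeneModels":
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
        transcripts: list[Transcript] = []
        for feat in db.features_of_type(("mRNA", "transcript")):
            exons = sorted(
                (c.start, c.end) for c in db.children(feat, featuretype="exon")
            )
            cds = sorted(
                (c.start, c.end) for c in db.children(feat, featuretype="CDS")
            )
            if not exons:
                exons = cds[:]
            transcripts.append(
                Transcript(feat.seqid, feat.start, feat.end, feat.strand, exons, cds)
            )
        return cls(transcripts)

    def consequence(
        self, genome: Genome, chrom: str, pos: int, ref: str, alt: str
    ) -> Consequence:
        tree = self._trees.get(chrom)
        hits = tree[pos] if tree is not None else ()
        if not hits:
            return Consequence("intergenic")
        best = Consequence("intronic")
        for hit in hits:
            c = self._classify_in_transcript(genome, hit.data, pos, ref, alt)
            if _SEVERITY[c.category] > _SEVERITY[best.category]:
                best = c
        return best

    @staticmethod
    def _classify_in_transcript(
        genome: Genome, t: Transcript, pos: int, ref: str, alt: str
    ) -> Consequence:
        in_exon = any(s <= pos <= e for s, e in t.exons)
        if not in_exon:
            near_boundary = any(
                0 < s - pos <= SPLICE_REGION or 0 < pos - e <= SPLICE_REGION
                for s, e in t.exons
            )
            return Consequence("splice_site" if near_boundary else "intronic")
        in_cds = any(s <= pos <= e for s, e in t.cds)
        if not in_cds:
            return Consequence("exonic")
        return _coding_consequence(genome, t, pos, ref, alt)


def _coding_consequence(
    genome: Genome, t: Transcript, pos: int, ref: str, alt: str
) -> Consequence:
    """Translate the affected codon before and after the substitution."""
    if t.strand == "+":
        coding = "".join(genome.slice(t.chrom, s, e) for s, e in t.cds)
        offset = 0
        for s, e in t.cds:
            if s <= pos <= e:
                offset += pos - s
                break
            offset += e - s + 1
        coding_alt = coding[:offset] + alt + coding[offset + 1 :]
    else:
        coding = "".join(
            revcomp(genome.slice(t.chrom, s, e)) for s, e in reversed(t.cds)
        )
        offset = 0
        for s, e in reversed(t.cds):
            if s <= pos <= e:
                offset += e - pos
                break
            offset += e - s + 1
        coding_alt = coding[:offset] + revcomp(alt) + coding[offset + 1 :]

    codon_idx = offset // 3
    start, stop = codon_idx * 3, codon_idx * 3 + 3
    if stop > len(coding):
        return Consequence("exonic")  # trailing partial codon
    aa_ref = str(Seq(coding[start:stop]).translate())
    aa_alt = str(Seq(coding_alt[start:stop]).translate())
    if aa_alt == "*" and aa_ref != "*":
        return Consequence("stop_gained", aa_ref, aa_alt)
    if aa_ref == aa_alt:
        return Consequence("synonymous", aa_ref, aa_alt)
    return Consequence("missense", aa_ref, aa_alt)
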