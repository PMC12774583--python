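"""Shared fixtures: a hand-crafted 300-bp alignment with known derived
variants, and small helpers used across test modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import pytest

from caddforge.ancestor import build_ancestor_map
from caddforge.genome import Genome
from caddforge.maf import AlignmentBlock, MafRow, revcomp
from caddforge.variants import PopulationAF


@dataclass
class HandcraftedAlignment:
    """300-bp toy: plus block (1-100) with an ancestor gap, minus-strand
    block (121-200), uncovered span (201-250), plus block (251-300) with an
    ancestor-insertion column. Ancestral edits are planted at five
    positions; two of them sit on polymorphic sites in the population VCF.
    """

    ref_seq: str = "ACGT" * 75
    # 1-based position -> planted ancestral base (reference differs there)
    edits: dict[int, str] = field(
        default_factory=lambda: {21: "G", 60: "C", 150: "T", 260: "A", 280: "G"}
    )
    gap_positions: tuple[int, ...] = (41, 42, 43)   # ancestor gap in block 1
    # population: (pos, alt, af); ref-allele AF is 1 - af
    pop_sites: tuple[tuple[int, str, float], ...] = (
        (260, "G", 0.5),    # ref AF 0.5 <= 0.9 -> derived call excluded
        (280, "C", 0.05),   # ref AF 0.95 > 0.9 -> derived call kept
    )

    @property
    def genome(self) -> Genome:
        return Genome({"chr1": self.ref_seq})

    @property
    def anc_seq(self) -> str:
        s = list(self.ref_seq)
        for pos, base in self.edits.items():
            assert s[pos - 1] != base
            s[pos - 1] = base
        return "".join(s)

    def blocks(self) -> list[AlignmentBlock]:
        ref, anc = self.ref_seq, self.anc_seq
        n = len(ref)

        # block 1: plus strand, positions 1-100, ancestor gap at 41-43
        anc1 = list(anc[0:100])
        for pos in self.gap_positions:
            anc1[pos - 1] = "-"
        b1 = AlignmentBlock(
            (
                MafRow("ref.chr1", 0, 100, "+", n, ref[0:100]),
                MafRow("Anc0.chr1", 0, 100 - len(self.gap_positions), "+", n, "".join(anc1)),
            )
        )

        # block 2: minus-strand reference row over forward positions 121-200
        s, e = 120, 200
        b2 = AlignmentBlock(
            (
                MafRow("ref.chr1", n - e, e - s, "-", n, revcomp(ref[s:e])),
                MafRow("Anc0.chr1", n - e, e - s, "-", n, revcomp(anc[s:e])),
            )
        )

        # block 3: plus strand, positions 251-300, with one ancestor-insertion
        # column (reference gap) after the 10th reference base
        ref3 = ref[250:300][:10] + "-" + ref[250:300][10:]
        anc3 = anc[250:300][:10] + "A" + anc[250:300][10:]
        b3 = AlignmentBlock(
            (
                MafRow("ref.chr1", 250, 50, "+", n, ref3),
                MafRow("Anc0.chr1", 250, 51, "+", n + 1, anc3),
            )
        )
        return [b1, b2, b3]

    def ancestor_map(self):
        return build_ancestor_map(
            self.blocks(), self.genome, "ref", ancestor_label="Anc0"
        )

    def population(self) -> PopulationAF:
        pop = PopulationAF()
        for pos, alt, af in self.pop_sites:
            pop.add("chr1", pos, alt, af)
        return pop

    def vcf_text(self) -> str:
        lines = [
            "##fileformat=VCFv4.2",
            '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">',
            "##contig=<ID=chr1,length=300>",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
        ]
        for pos, alt, af in self.pop_sites:
            ref = self.ref_seq[pos - 1]
            lines.append(f"chr1\t{pos}\t.\t{ref}\t{alt}\t.\t.\tAF={af}")
        return "\n".join(lines) + "\n"

    def expected_derived(self, with_population: bool) -> list[tuple[int, str, str]]:
        """Hand-enumerated (pos, from=ancestral, to=reference) calls."""
        calls = [
            (21, "G", "A"),
            (60, "C", "T"),
            (150, "T", "C"),
            (260, "A", "T"),
            (280, "G", "T"),
        ]
        if with_population:
            calls = [c for c in calls if c[0] != 260]
        return calls


@pytest.fixture(scope="session")
def handcrafted() -> HandcraftedAlignment:
    return HandcraftedAlignment()
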