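"""Ancestor-map construction: strand handling, conflicts, consensus modes,
coverage statistics and serialization."""

import numpy as np
import pytest

from caddforge.ancestor import (
    AMBIGUOUS,
    UNALIGNED,
    AncestorMap,
    AncestorMapError,
    build_ancestor_map,
    coverage_stats,
)
from caddforge.genome import Genome
from caddforge.maf import AlignmentBlock, MafRow, revcomp


def _block(ref_text, anc_text, start=0, src_size=None, strand="+", anc_label="Anc0"):
    src_size = src_size or (start + sum(c != "-" for c in ref_text))
    return AlignmentBlock(
        (
            MafRow("ref.chr1", start, sum(c != "-" for c in ref_text), strand, src_size, ref_text),
            MafRow(f"{anc_label}.chr1", start, sum(c != "-" for c in anc_text), strand, src_size, anc_text),
        )
    )


def test_identity_block_reproduces_reference():
    seq = "ACGTACGTACGTACGTACGT"
    genome = Genome({"chr1": seq})
    amap = build_ancestor_map([_block(seq, seq)], genome, "ref", ancestor_label="Anc0")
    assert all(amap.get("chr1", i + 1) == seq[i] for i in range(len(seq)))


def test_single_mismatch_at_offset_12():
    # 60-bp block; ancestor carries C where the reference carries T at offset 12
    ref = ("TCA" * 20)[:60]
    assert ref[12] == "T"
    anc = ref[:12] + "C" + ref[13:]
    genome = Genome({"chr1": ref})
    amap = build_ancestor_map([_block(ref, anc)], genome, "ref", ancestor_label="Anc0")
    assert amap.get("chr1", 13) == "C"
    for i in range(60):
        if i != 12:
            assert amap.get("chr1", i + 1) == ref[i]


def test_overlapping_blocks_conflict_is_ambiguous():
    ref = "AAAA"
    genome = Genome({"chr1": ref})
    b1 = _block("AAAA", "AAAA")
    b2 = _block("AAAA", "AGAA")  # disagrees at position 2
    amap = build_ancestor_map([b1, b2], genome, "ref", ancestor_label="Anc0")
    assert amap.get("chr1", 2) == AMBIGUOUS
    assert amap.get("chr1", 1) == "A"


def test_ancestor_gap_and_uncovered_positions_are_unaligned(handcrafted):
    amap = handcrafted.ancestor_map()
    for pos in handcrafted.gap_positions:
        assert amap.get("chr1", pos) == UNALIGNED
    for pos in (101, 120, 201, 250):
        assert amap.get("chr1", pos) == UNALIGNED
    assert amap.get("chr1", 150) == "T"     # planted edit inside the minus block


def test_strand_flip_property(handcrafted):
    """Reverse-complementing every row and flipping strands leaves the map
    unchanged."""
    flipped = []
    for block in handcrafted.blocks():
        rows = tuple(
            MafRow(
                r.src,
                r.src_size - r.start - r.size,
                r.size,
                "-" if r.strand == "+" else "+",
                r.src_size,
                revcomp(r.text),
            )
            for r in block.rows
        )
        flipped.append(AlignmentBlock(rows))
    original = handcrafted.ancestor_map()
    mirrored = build_ancestor_map(
        flipped, handcrafted.genome, "ref", ancestor_label="Anc0"
    )
    for chrom in original.chroms:
        assert np.array_equal(original.array(chrom), mirrored.array(chrom))


def test_outgroup_consensus_modes():
    ref = "ACGTACGT"
    genome = Genome({"chr1": ref})
    rows = (
        MafRow("ref.chr1", 0, 8, "+", 8, ref),
        MafRow("out1.chr1", 0, 8, "+", 8, "ACGTACGA"),
        MafRow("out2.chr1", 0, 8, "+", 8, "ACGTACGC"),
        MafRow("out3.chr1", 0, 8, "+", 8, "ACGTACGC"),
    )
    block = AlignmentBlock(rows)
    strict = build_ancestor_map(
        [block], genome, "ref",
        outgroup_labels=["out1", "out2", "out3"], strategy="strict_consensus",
    )
    # all agree on the first 7 positions; the last disagrees -> unaligned
    assert strict.get("chr1", 7) == "G"
    assert strict.get("chr1", 8) == UNALIGNED
    majority = build_ancestor_map(
        [block], genome, "ref",
        outgroup_labels=["out1", "out2", "out3"], strategy="majority",
    )
    assert majority.get("chr1", 8) == "C"   # 2 of 3 outgroups
    # two-way tie -> ambiguous
    tie = AlignmentBlock(rows[:3])
    tie_map = build_ancestor_map(
        [tie], genome, "ref", outgroup_labels=["out1", "out2"], strategy="majority"
    )
    assert tie_map.get("chr1", 8) == AMBIGUOUS


def test_missing_species_errors():
    genome = Genome({"chr1": "ACGT"})
    block = _block("ACGT", "ACGT")
    with pytest.raises(AncestorMapError, match="nosuch"):
        build_ancestor_map([block], genome, "nosuch", ancestor_label="Anc0")
    with pytest.raises(AncestorMapError, match="AncX"):
        build_ancestor_map([block], genome, "ref", ancestor_label="AncX")
    with pytest.raises(AncestorMapError, match="exactly one"):
        build_ancestor_map([block], genome, "ref")


def test_coverage_stats_counts(handcrafted):
    genome = handcrafted.genome
    amap = handcrafted.ancestor_map()
    stats = coverage_stats(amap, genome)
    # covered: blocks span 100 + 80 + 50 positions, minus 3 ancestor gaps
    assert stats["chr1"] == pytest.approx((100 + 80 + 50 - 3) / 300)
    assert stats["total"] == stats["chr1"]

    full = AncestorMap({"chr1": 4})
    for i, b in enumerate("ACGT", start=1):
        full.set("chr1", i, b)
    g4 = Genome({"chr1": "ACGT"})
    assert coverage_stats(full, g4)["chr1"] == 1.0
    empty = AncestorMap({"chr1": 4})
    assert coverage_stats(empty, g4)["chr1"] == 0.0
    with pytest.raises(AncestorMapError):
        coverage_stats(full, Genome({"chr2": "ACGT"}))


def test_coverage_total_is_weighted_sum():
    g = Genome({"chr1": "ACGTACGTAC", "chr2": "ACGTA"})
    amap = AncestorMap({"chr1": 10, "chr2": 5})
    for pos in (1, 2, 3, 4, 5, 6, 7, 8):
        amap.set("chr1", pos, "A")
    for pos in (1, 2):
        amap.set("chr2", pos, "C")
    stats = coverage_stats(amap, g)
    assert stats["chr1"] == 0.8
    assert stats["chr2"] == pytest.approx(0.4)
    assert stats["total"] == pytest.approx((8 + 2) / 15)


def test_tsv_round_trip(tmp_path, handcrafted):
    amap = handcrafted.ancestor_map()
    path = tmp_path / "anc.tsv"
    amap.to_tsv(path)
    again = AncestorMap.from_tsv(path, {"chr1": 300})
    assert np.array_equal(amap.array("chr1"), again.array("chr1"))
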