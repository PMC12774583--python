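"""Windowed substitution-rate estimation and proxy-deleterious simulation.

Local mutation rates are the per-window frequencies of ancestor->reference
base substitutions among aligned sites: within each window of
``window_size`` bp, ``r[from, to] = C[from, to] / base_counts[from]`` where
``base_counts[from]`` counts aligned positions whose ancestral base is
``from``. Sparse windows (fewer aligned bases than ``min_window_bases``)
fall back to the genome-wide matrix.

The simulator draws reference->alt substitutions without replacement over
(position, alt) pairs, weighting each candidate by its window's rate for
that substitution type, excluding alleles seen in the population above
``af_exclude`` (default 10%) and any (position, allele) already claimed by
the derived set.
"""

from __future__ import annotations

import json
import os

import numpy as np

from .ancestor import AncestorMap
from .genome import Genome
from .variants import SNV, PopulationAF

BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i


class RateModelError(ValueError):
    pass


class SimulationError(ValueError):
    pass


class MutationRateModel:
    """Per-window 4x4 ancestor->reference substitution counts and rates."""

    def __init__(
        self,
        window_size: int,
        counts: dict[str, np.ndarray],        # (n_windows, 4, 4) int64
        base_counts: dict[str, np.ndarray],   # (n_windows, 4) int64
        min_window_bases: int = 1000,
    ):
        self.window_size = int(window_size)
        self.counts = counts
        self.base_counts = base_counts
        self.min_window_bases = int(min_window_bases)
        self.genome_wide_counts = sum(c.sum(axis=0) for c in counts.values())
        self.genome_wide_bases = sum(b.sum(axis=0) for b in base_counts.values())
        self._rates = {c: self._window_rates(c) for c in counts}
        self.fallback_windows = {
            c: int(
                (self.base_counts[c].sum(axis=1) < self.min_window_bases).sum()
            )
            for c in counts
        }

    @staticmethod
    def _divide(c: np.ndarray, b: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = c / b[..., :, None]
        return np.nan_to_num(r, nan=0.0, posinf=0.0)

    def _window_rates(self, chrom: str) -> np.ndarray:
        local = self._divide(
            self.counts[chrom].astype(float), self.base_counts[chrom].astype(float)
        )
        global_r = self.genome_wide_rates()
        sparse = self.base_counts[chrom].sum(axis=1) < self.min_window_bases
        local[sparse] = global_r
        return local

    def genome_wide_rates(self) -> np.ndarray:
        return self._divide(
            self.genome_wide_counts.astype(float),
            self.genome_wide_bases.astype(float),
        )

    def rates(self, chrom: str) -> np.ndarray:
        """(n_windows, 4, 4) rate array with sparse-window fallback applied."""
        return self._rates[chrom]

    def window_index(self, pos: int) -> int:
        """Window index of a 1-based position."""
        return (pos - 1) // self.window_size

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "window_size": self.window_size,
            "min_window_bases": self.min_window_bases,
            "bases": BASES,
            "counts": {c: a.tolist() for c, a in self.counts.items()},
            "base_counts": {c: a.tolist() for c, a in self.base_counts.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "MutationRateModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            window_size=payload["window_size"],
            counts={c: np.asarray(a, dtype=np.int64) for c, a in payload["counts"].items()},
            base_counts={
                c: np.asarray(a, dtype=np.int64) for c, a in payload["base_counts"].items()
            },
            min_window_bases=payload["min_window_bases"],
        )


def estimate_mutation_rates(
    genome: Genome,
    anc: AncestorMap,
    window_size: int = 100_000,
    min_window_bases: int = 1000,
) -> MutationRateModel:
    """Count ancestor->reference substitutions per window and derive rates."""
    if window_size < 1:
        raise RateModelError(f"window_size must be >= 1, got {window_size}")
    counts: dict[str, np.ndarray] = {}
    base_counts: dict[str, np.ndarray] = {}
    any_aligned = False
    for chrom in anc.chroms:
        n = genome.length(chrom)
        n_windows = max(1, -(-n // window_size))
        c = np.zeros((n_windows, 4, 4), dtype=np.int64)
        b = np.zeros((n_windows, 4), dtype=np.int64)
        arr = anc.array(chrom)
        ref = np.frombuffer(genome[chrom].encode("ascii"), dtype=np.uint8)
        anc_code = _CODE[arr]
        ref_code = _CODE[ref]
        aligned = anc.concrete_mask(chrom) & (ref_code != 255)
        if aligned.any():
            any_aligned = True
            pos0 = np.nonzero(aligned)[0]
            widx = pos0 // window_size
            np.add.at(b, (widx, anc_code[pos0]), 1)
            mism = pos0[anc_code[pos0] != ref_code[pos0]]
            if len(mism):
                np.add.at(
                    c,
                    (mism // window_size, anc_code[mism], ref_code[mism]),
                    1,
                )
        counts[chrom] = c
        base_counts[chrom] = b
    if not any_aligned:
        raise RateModelError("no aligned positions: cannot build a rate model")
    return MutationRateModel(window_size, counts, base_counts, min_window_bases)


def simulate_variants(
    model: MutationRateModel,
    genome: Genome,
    anc: AncestorMap,
    n_target: int,
    pop: PopulationAF | None = None,
    af_exclude: float = 0.1,
    seed: int = 0,
    exclude: set[tuple[str, int, str]] | None = None,
) -> list[SNV]:
    """Draw ``n_target`` simulated SNVs without replacement.

    Sampling uses Gumbel perturbation of log-weights (equivalent to
    successive weighted draws without replacement), so output is a
    deterministic function of the seed and the candidate enumeration order.
    ``exclude`` holds (chrom, pos, allele) keys — typically the derived
    set — that may never be emitted.
    """
    if n_target < 0:
        raise SimulationError(f"n_target must be >= 0, got {n_target}")
    if not 0.0 <= af_exclude <= 1.0:
        raise SimulationError(f"af_exclude must lie in [0,1], got {af_exclude}")
    if n_target == 0:
        return []
    if model.genome_wide_counts.sum() == 0:
        raise SimulationError("all-zero rate model: nothing to simulate from")

    chroms = list(anc.chroms)
    cand_chrom: list[np.ndarray] = []
    cand_pos0: list[np.ndarray] = []
    cand_alt: list[np.ndarray] = []
    cand_w: list[np.ndarray] = []

    for ci, chrom in enumerate(chroms):
        ref = np.frombuffer(genome[chrom].encode("ascii"), dtype=np.uint8)
        ref_code = _CODE[ref]
        aligned = anc.concrete_mask(chrom) & (ref_code != 255)
        pos0 = np.nonzero(aligned)[0]
        if not len(pos0):
            continue
        rates = model.rates(chrom)
        widx = pos0 // model.window_size
        rc = ref_code[pos0]
        excl_codes = _exclusion_codes(chrom, pop, af_exclude, exclude)
        for alt in range(4):
            valid = rc != alt
            w = rates[widx[valid], rc[valid], alt]
            p = pos0[valid]
            keep = w > 0
            p, w = p[keep], w[keep]
            if excl_codes is not None and len(p):
                keep2 = ~np.isin(p.astype(np.int64) * 4 + alt, excl_codes)
                p, w = p[keep2], w[keep2]
            if len(p):
                cand_chrom.append(np.full(len(p), ci, dtype=np.uint16))
                cand_pos0.append(p)
                cand_alt.append(np.full(len(p), alt, dtype=np.uint8))
                cand_w.append(w)

    if not cand_pos0:
        raise SimulationError(f"candidate pool is empty, needed {n_target}")
    chrom_a = np.concatenate(cand_chrom)
    pos0_a = np.concatenate(cand_pos0)
    alt_a = np.concatenate(cand_alt)
    w_a = np.concatenate(cand_w)
    pool = len(w_a)
    if pool < n_target:
        raise SimulationError(
            f"candidate pool has {pool} entries, fewer than n_target={n_target}"
        )

    rng = np.random.default_rng(seed)
    keys = np.log(w_a) + rng.gumbel(size=pool)
    top = np.argpartition(keys, pool - n_target)[pool - n_target :]
    # deterministic output order: chromosome, position, alt allele
    order = np.lexsort((alt_a[top], pos0_a[top], chrom_a[top]))
    sel = top[order]

    out: list[SNV] = []
    for ci, p0, alt in zip(chrom_a[sel], pos0_a[sel], alt_a[sel]):
        chrom = chroms[int(ci)]
        pos = int(p0) + 1
        to = BASES[int(alt)]
        out.append(
            SNV(
                chrom=chrom,
                pos=pos,
                from_allele=genome.base(chrom, pos),
                to_allele=to,
                class_label="simulated",
                af=pop.get(chrom, pos, to) if pop is not None else None,
            )
        )
    return out


def _exclusion_codes(
    chrom: str,
    pop: PopulationAF | None,
    af_exclude: float,
    exclude: set[tuple[str, int, str]] | None,
) -> np.ndarray | None:
    """Encode excluded (pos0, alt) pairs as pos0*4+alt for fast isin tests."""
    codes: list[int] = []
    if pop is not None:
        for (c, pos, alt), af in pop.af.items():
            if c == chrom and af > af_exclude:
                codes.append((pos - 1) * 4 + BASES.index(alt))
    if exclude:
        for c, pos, alt in exclude:
            if c == chrom:
                codes.append((pos - 1) * 4 + BASES.index(alt))
    if not codes:
        return None
    return np.unique(np.asarray(codes, dtype=np.int64))
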