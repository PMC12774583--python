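"""Exhaustive SNV enumeration, model scoring and PHRED-like scaling.

Every position with a concrete reference base contributes its three
alternate alleles. Raw scores are the classifier's linear predictor
(higher = more proxy-deleterious-like); the final score of the variant with
rank ``i`` out of ``N`` (rank 1 = highest raw score) is ``-10*log10(i/N)``,
so ranks are what matter and any monotone transform of the raw score leaves
the output unchanged. Ties share the minimum rank of their tie group.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .consequence import GeneModels
from .features import FeatureSpec, assemble_features, encode_and_impute
from .genome import VALID_BASES, Genome
from .model import TrainedModel
from .tracks import AnnotationTrack

ALT_ORDER = "ACGT"
_BASE_ARR = np.array(list(ALT_ORDER))
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(ALT_ORDER):
    _CODE[ord(_b)] = _i
# the three alternates of each reference base, in A<C<G<T order
_ALT_TABLE = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])


class ScoringError(ValueError):
    pass


def enumerate_snvs(
    genome: Genome,
    region: tuple[str, int, int] | None = None,
    chunk_size: int = 200_000,
) -> Iterator[pd.DataFrame]:
    """Yield (chrom, pos, ref, alt) frames, 3 rows per non-N position.

    Alternates appear in fixed order A<C<G<T (skipping the reference base);
    positions ascend within each chromosome. ``region`` is a 1-based
    inclusive (chrom, start, end) restriction.
    """
    if region is not None:
        chrom, start, end = region
        if chrom not in genome:
            raise ScoringError(f"region chromosome {chrom!r} not in the genome")
        if not (1 <= start <= end <= genome.length(chrom)):
            raise ScoringError(f"region {chrom}:{start}-{end} out of bounds")
        spans = [(chrom, start, end)]
    else:
        spans = [(c, 1, genome.length(c)) for c in genome]

    for chrom, start, end in spans:
        for lo in range(start, end + 1, chunk_size):
            hi = min(lo + chunk_size - 1, end)
            seq = genome.slice(chrom, lo, hi)
            b = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            code = _CODE[b]
            pos = np.nonzero(code >= 0)[0]
            if not len(pos):
                continue
            refs = code[pos]
            yield pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": np.repeat(pos + lo, 3).astype(np.int64),
                    "from": _BASE_ARR[np.repeat(refs, 3)],
                    "to": _BASE_ARR[_ALT_TABLE[refs].reshape(-1)],
                }
            )


def raw_score(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Linear predictor for encoded rows (see TrainedModel.decision_values)."""
    return model.decision_values(np.atleast_2d(X))


def phred_scale(raw_scores: np.ndarray) -> np.ndarray:
    """-10*log10(i/N) with i the (min-method) descending rank of each score."""
    raw_scores = np.asarray(raw_scores, dtype=float)
    if raw_scores.size == 0:
        raise ScoringError("phred_scale needs at least one score")
    if not np.isfinite(raw_scores).all():
        raise ScoringError("raw scores must be finite")
    ranks = rankdata(-raw_scores, method="min")
    return -10.0 * np.log10(ranks / raw_scores.size) + 0.0   # +0.0 kills -0.0


@dataclass
class ScoreTable:
    rows: pd.DataFrame      # chrom, pos, ref, alt, raw_score, phred
    region_label: str       # provenance of the ranked set ("genome" or region)

    @property
    def n(self) -> int:
        return len(self.rows)


def score_variants(
    genome: Genome,
    model: TrainedModel,
    specs: list[FeatureSpec],
    tracks: dict[str, AnnotationTrack],
    region: tuple[str, int, int] | None = None,
    context_window: int = 75,
    gene_models: GeneModels | None = None,
    chunk_size: int = 200_000,
) -> ScoreTable:
    """Enumerate, annotate, score and PHRED-scale all SNVs (two passes over
    the enumeration: the rank set is global over the scored region)."""
    if model.imputation_stats is None:
        raise ScoringError("model carries no imputation statistics")
    frames: list[pd.DataFrame] = []
    for keys in enumerate_snvs(genome, region, chunk_size):
        records = assemble_features(
            keys, specs, tracks, genome, context_window, gene_models
        )
        fm = encode_and_impute(
            records, specs, labels=None, row_keys=keys, stats=model.imputation_stats
        )
        keys = keys.copy()
        keys["raw_score"] = model.decision_values(fm.X)
        frames.append(keys)
    if not frames:
        table = pd.DataFrame(columns=["chrom", "pos", "from", "to", "raw_score"])
    else:
        table = pd.concat(frames, ignore_index=True)
    table = table.rename(columns={"from": "ref", "to": "alt"})
    if len(table):
        table["phred"] = phred_scale(table["raw_score"].to_numpy())
    else:
        table["phred"] = np.zeros(0)
    label = "genome" if region is None else f"{region[0]}:{region[1]}-{region[2]}"
    return ScoreTable(rows=table, region_label=label)


def write_scores(table: ScoreTable, path: str | os.PathLike) -> None:
    """Coordinate-sorted TSV: '#Chrom Pos Ref Alt RawScore PHRED' (tab
    separated; PHRED to 3 decimals), suitable for bgzip + tabix indexing."""
    df = table.rows
    if len(df):
        key = pd.MultiIndex.from_arrays(
            [pd.factorize(df["chrom"])[0], df["pos"], df["alt"]]
        )
        if not key.is_monotonic_increasing:
            raise ScoringError("score table is not sorted by (chrom, pos, alt)")
    with open(path, "w") as fh:
        fh.write(f"##ranked_set={table.region_label};N={len(df)}\n")
        fh.write("#Chrom\tPos\tRef\tAlt\tRawScore\tPHRED\n")
        for chrom, pos, ref, alt, raw, phred in df[
            ["chrom", "pos", "ref", "alt", "raw_score", "phred"]
        ].itertuples(index=False):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{raw:.6g}\t{phred:.3f}\n")


def read_scores(path: str | os.PathLike) -> ScoreTable:
    label = "genome"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("##ranked_set="):
            label = first.split("=", 1)[1].split(";")[0]
    df = pd.read_csv(
        path,
        sep="\t",
        comment=None,
        skiprows=1,
        dtype={"#Chrom": str},
    )
    df = df.rename(
        columns={
            "#Chrom": "chrom",
            "Pos": "pos",
            "Ref": "ref",
            "Alt": "alt",
            "RawScore": "raw_score",
            "PHRED": "phred",
        }
    )
    return ScoreTable(rows=df, region_label=label)


def score_summary_by_consequence(
    table: ScoreTable,
    genome: Genome,
    gene_models: GeneModels,
) -> pd.DataFrame:
    """Distribution of PHRED scores per functional-consequence category."""
    df = table.rows
    categories = [
        gene_models.consequence(genome, c, int(p), r, a).category
        for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
    ]
    out = (
        df.assign(consequence=categories)
        .groupby("consequence")["phred"]
        .agg(["count", "mean", "median", "max"])
        .reset_index()
        .sort_values("mean", ascending=False, ignore_index=True)
    )
    return out
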