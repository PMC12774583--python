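"""Feature assembly, one-hot encoding and missing-value imputation.

Raw records are a variant x feature frame (NaN/None = missing) built from
annotation tracks and built-in sequence features. Encoding turns them into
a fully finite numeric matrix: categoricals become one-hot groups over
declared levels, and missing values are handled per feature by one of

* ``indicator``            — fill 0 and set a companion 0/1 missing column,
* ``mean_from_simulated``  — fill with the mean over simulated-class rows
                             only (stored for reuse at scoring time),
* ``fixed``                — fill with a configured constant.

The encoded column layout is a pure function of the feature specs, so
training- and scoring-time matrices always align.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .consequence import GeneModels
from .genome import Genome
from .grantham import grantham
from .tracks import AnnotationTrack
from .variants import SNV

BUILTIN_FEATURES = ("gc_fraction", "cpg_count", "ref_base", "consequence", "grantham")


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    source: str                    # track name or one of BUILTIN_FEATURES
    kind: str                      # 'numeric' | 'categorical'
    imputation: str = "indicator"  # 'indicator' | 'mean_from_simulated' | 'fixed'
    fixed_value: float | None = None
    levels: tuple[str, ...] = dc_field(default_factory=tuple)

    def __post_init__(self):
        if self.kind not in ("numeric", "categorical"):
            raise FeatureError(f"{self.name}: bad kind {self.kind!r}")
        if self.imputation not in ("indicator", "mean_from_simulated", "fixed"):
            raise FeatureError(f"{self.name}: bad imputation {self.imputation!r}")
        if self.imputation == "fixed" and (
            self.fixed_value is None or not np.isfinite(self.fixed_value)
        ):
            raise FeatureError(f"{self.name}: fixed imputation needs a finite value")
        if self.kind == "categorical":
            if self.imputation != "indicator":
                raise FeatureError(
                    f"{self.name}: categorical features support indicator imputation only"
                )
            if not self.levels:
                raise FeatureError(f"{self.name}: categorical feature needs levels")

    def encoded_columns(self) -> list[str]:
        if self.kind == "numeric":
            cols = [self.name]
        else:
            cols = [f"{self.name}={lvl}" for lvl in self.levels]
        if self.imputation == "indicator" or self.kind == "categorical":
            cols.append(f"{self.name}__missing")
        return cols


# -- built-in sequence-context features -----------------------------------

def context_feature_arrays(
    seq: str, positions: np.ndarray, window: int = 75
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized GC fraction and CpG count around 1-based ``positions``.

    Windows are [pos-window, pos+window], clipped at sequence ends. The GC
    denominator counts non-N bases; all-N windows yield NaN GC fraction.
    """
    b = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = len(b)
    is_gc = ((b == ord("G")) | (b == ord("C"))).astype(np.int64)
    not_n = (b != ord("N")).astype(np.int64)
    is_cpg_start = np.zeros(n, dtype=np.int64)
    if n > 1:
        is_cpg_start[:-1] = (b[:-1] == ord("C")) & (b[1:] == ord("G"))
    cum_gc = np.concatenate(([0], np.cumsum(is_gc)))
    cum_nn = np.concatenate(([0], np.cumsum(not_n)))
    cum_cpg = np.concatenate(([0], np.cumsum(is_cpg_start)))

    lo = np.clip(positions - 1 - window, 0, n)          # 0-based inclusive
    hi = np.clip(positions - 1 + window + 1, 0, n)      # 0-based exclusive
    gc = (cum_gc[hi] - cum_gc[lo]).astype(float)
    nn = (cum_nn[hi] - cum_nn[lo]).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        gc_frac = np.where(nn > 0, gc / nn, np.nan)
    # a CpG lies in the window when both bases do: starts in [lo, hi-2]
    cpg_hi = np.maximum(hi - 1, lo)
    cpg = (cum_cpg[cpg_hi] - cum_cpg[lo]).astype(float)
    return gc_frac, cpg


def sequence_context_features(
    genome: Genome, chrom: str, pos: int, window: int = 75
) -> dict[str, object]:
    """GC fraction, CpG count and reference base around one position."""
    if not 1 <= pos <= genome.length(chrom):
        raise FeatureError(f"position {chrom}:{pos} outside the chromosome")
    gc, cpg = context_feature_arrays(genome[chrom], np.asarray([pos]), window)
    return {
        "gc_fraction": float(gc[0]),
        "cpg_count": float(cpg[0]),
        "ref_base": genome.base(chrom, pos),
    }


# -- raw-record assembly ---------------------------------------------------

def variants_frame(variants: list[SNV]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [v.chrom for v in variants],
            "pos": np.asarray([v.pos for v in variants], dtype=np.int64),
            "from": [v.from_allele for v in variants],
            "to": [v.to_allele for v in variants],
            "class": [v.class_label for v in variants],
        }
    )


def assemble_features(
    keys: pd.DataFrame,
    specs: list[FeatureSpec],
    tracks: dict[str, AnnotationTrack],
    genome: Genome,
    context_window: int = 75,
    gene_models: GeneModels | None = None,
) -> pd.DataFrame:
    """Per-variant raw feature records; absent annotations become missing.

    ``keys`` needs columns chrom/pos/from/to. Per-position tracks join on
    (chrom, pos); per-variant tracks on the full allele-resolved key.
    """
    records = pd.DataFrame(index=keys.index)
    consequences: pd.Series | None = None

    for spec in specs:
        if spec.source in BUILTIN_FEATURES:
            if spec.source in ("gc_fraction", "cpg_count"):
                records[spec.name] = _builtin_context(
                    keys, genome, spec.source, context_window
                )
            elif spec.source == "ref_base":
                records[spec.name] = [
                    genome.base(c, int(p)) for c, p in zip(keys["chrom"], keys["pos"])
                ]
            elif spec.source in ("consequence", "grantham"):
                if gene_models is None:
                    raise FeatureError(
                        f"feature {spec.name!r} needs gene models (GFF3) to compute"
                    )
                if consequences is None:
                    consequences = _call_consequences(keys, genome, gene_models)
                if spec.source == "consequence":
                    records[spec.name] = [c.category for c in consequences]
                else:
                    records[spec.name] = [
                        float(g)
                        if c.category == "missense"
                        and (g := grantham(c.aa_ref, c.aa_alt)) is not None
                        else np.nan
                        for c in consequences
                    ]
        elif spec.source in tracks:
            track = tracks[spec.source]
            merged = keys.merge(track.data, how="left", on=track.key_columns)
            values = merged["value"].to_numpy()
            if spec.kind == "numeric":
                records[spec.name] = pd.to_numeric(values, errors="coerce")
            else:
                records[spec.name] = [
                    None if pd.isna(v) else str(v) for v in values
                ]
        else:
            raise FeatureError(
                f"feature {spec.name!r}: unknown source {spec.source!r} "
                f"(not a loaded track or builtin)"
            )
    return records


def _builtin_context(keys, genome, which, window) -> np.ndarray:
    out = np.full(len(keys), np.nan)
    arr = keys["pos"].to_numpy()
    for chrom in keys["chrom"].unique():
        mask = (keys["chrom"] == chrom).to_numpy()
        gc, cpg = context_feature_arrays(genome[chrom], arr[mask], window)
        out[mask] = gc if which == "gc_fraction" else cpg
    return out


def _call_consequences(keys, genome, gene_models) -> list:
    return [
        gene_models.consequence(genome, c, int(p), f, t)
        for c, p, f, t in zip(keys["chrom"], keys["pos"], keys["from"], keys["to"])
    ]


# -- encoding and imputation ----------------------------------------------

@dataclass
class FeatureMatrix:
    row_keys: pd.DataFrame
    column_names: list[str]
    X: np.ndarray
    y: np.ndarray | None
    imputation_stats: dict[str, float]

    def __post_init__(self):
        if not np.isfinite(self.X).all():
            raise FeatureError("encoded matrix contains non-finite entries")
        if self.y is not None and len(self.y) != self.X.shape[0]:
            raise FeatureError("label/matrix length mismatch")


def encode_and_impute(
    records: pd.DataFrame,
    specs: list[FeatureSpec],
    labels: np.ndarray | None,
    row_keys: pd.DataFrame | None = None,
    stats: dict[str, float] | None = None,
) -> FeatureMatrix:
    """Encode raw records into a finite matrix.

    ``labels``: 1 = simulated (proxy-deleterious), 0 = derived. At training
    time ``stats`` is None and simulated-class means are computed here; at
    scoring time pass the training ``imputation_stats`` so no statistic is
    ever recomputed from the scored variants.
    """
    n = len(records)
    training = stats is None
    out_stats: dict[str, float] = {} if training else dict(stats)
    columns: list[np.ndarray] = []
    names: list[str] = []

    for spec in specs:
        col = records[spec.name]
        if spec.kind == "numeric":
            values = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
            missing = ~np.isfinite(values)
            if spec.imputation == "indicator":
                filled = np.where(missing, 0.0, values)
            elif spec.imputation == "fixed":
                filled = np.where(missing, spec.fixed_value, values)
            else:  # mean_from_simulated
                if training:
                    if labels is None:
                        raise FeatureError(
                            f"{spec.name}: mean_from_simulated needs class labels"
                        )
                    sim = values[(labels == 1) & ~missing]
                    if not len(sim):
                        raise FeatureError(
                            f"{spec.name}: no simulated-class values to take the mean of"
                        )
                    out_stats[spec.name] = float(sim.mean())
                if spec.name not in out_stats:
                    raise FeatureError(
                        f"{spec.name}: no stored imputation mean from training"
                    )
                filled = np.where(missing, out_stats[spec.name], values)
            columns.append(filled)
            names.append(spec.name)
            if spec.imputation == "indicator":
                columns.append(missing.astype(float))
                names.append(f"{spec.name}__missing")
        else:
            s = col.astype("string")
            known = s.isin(spec.levels).fillna(False).to_numpy(dtype=bool)
            for lvl in spec.levels:
                eq = (s == lvl).fillna(False).to_numpy(dtype=float)
                columns.append(eq)
                names.append(f"{spec.name}={lvl}")
            columns.append((~known).astype(float))
            names.append(f"{spec.name}__missing")

    X = np.column_stack(columns) if columns else np.empty((n, 0))
    return FeatureMatrix(
        row_keys=row_keys if row_keys is not None else pd.DataFrame(index=records.index),
        column_names=names,
        X=X,
        y=None if labels is None else np.asarray(labels, dtype=np.int64),
        imputation_stats=out_stats,
    )


# -- pipeline artifact I/O -------------------------------------------------

def save_feature_matrix(fm: FeatureMatrix, path: str | os.PathLike) -> None:
    df = fm.row_keys.reset_index(drop=True).copy()
    for j, name in enumerate(fm.column_names):
        df[name] = fm.X[:, j]
    if fm.y is not None:
        df["__label__"] = fm.y
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_feature_matrix(path: str | os.PathLike, stats: dict[str, float]) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    key_cols = [c for c in ("chrom", "pos", "from", "to", "class") if c in df.columns]
    y = df["__label__"].to_numpy(dtype=np.int64) if "__label__" in df.columns else None
    feature_cols = [c for c in df.columns if c not in key_cols + ["__label__"]]
    return FeatureMatrix(
        row_keys=df[key_cols],
        column_names=feature_cols,
        X=df[feature_cols].to_numpy(dtype=float),
        y=y,
        imputation_stats=stats,
    )


def save_imputation_stats(stats: dict[str, float], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(stats, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_imputation_stats(path: str | os.PathLike) -> dict[str, float]:
    with open(path) as fh:
        return json.load(fh)
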