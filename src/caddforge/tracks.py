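"""Annotation-track loading: bedGraph/wig, BED interval states, per-variant
TSV, and VCF INFO fields.

Interval formats (0-based half-open) are expanded to per-position lookups in
1-based coordinates at load time; per-variant sources key on
(chrom, pos, from, to). All tracks are held as a pandas DataFrame so the
feature-assembly layer can join them onto variant frames with merges.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .genome import Genome

logger = logging.getLogger(__name__)

POSITION_KEY = ["chrom", "pos"]
VARIANT_KEY = ["chrom", "pos", "from", "to"]


class TrackError(ValueError):
    pass


@dataclass
class AnnotationTrack:
    name: str
    kind: str                      # 'numeric' | 'categorical'
    resolution: str                # 'per_position' | 'per_variant'
    data: pd.DataFrame             # key columns + 'value'
    skipped_out_of_range: int = 0
    levels: tuple[str, ...] = field(default_factory=tuple)

    @property
    def key_columns(self) -> list[str]:
        return POSITION_KEY if self.resolution == "per_position" else VARIANT_KEY

    def lookup(self, chrom: str, pos: int, frm: str | None = None, to: str | None = None):
        """Single-key lookup; returns None when absent."""
        df = self.data
        mask = (df["chrom"] == chrom) & (df["pos"] == pos)
        if self.resolution == "per_variant":
            mask &= (df["from"] == frm) & (df["to"] == to)
        hit = df.loc[mask, "value"]
        return None if hit.empty else hit.iloc[0]


def load_track(
    path: str | os.PathLike,
    fmt: str,
    name: str,
    kind: str,
    genome: Genome | None = None,
    value_column: str | None = None,
    info_field: str | None = None,
) -> AnnotationTrack:
    """Load one annotation source.

    fmt: 'bedgraph', 'wig', 'bed', 'tsv' or 'vcf-info'. Coordinates outside
    the genome (when a genome is given) are skipped with a logged count;
    unparseable lines raise with their line number.
    """
    fmt = fmt.lower()
    if fmt in ("bedgraph", "wig"):
        df, skipped = _load_wiggle(path, fmt, genome)
        track = AnnotationTrack(name, kind, "per_position", df, skipped)
    elif fmt == "bed":
        df, skipped = _load_bed(path, genome)
        track = AnnotationTrack(name, kind, "per_position", df, skipped)
    elif fmt == "tsv":
        df, skipped = _load_variant_tsv(path, value_column or "value", genome)
        track = AnnotationTrack(name, kind, "per_variant", df, skipped)
    elif fmt == "vcf-info":
        if info_field is None:
            raise TrackError(f"track {name!r}: vcf-info format needs info_field")
        df = _load_vcf_info(path, info_field)
        track = AnnotationTrack(name, kind, "per_variant", df)
    else:
        raise TrackError(f"track {name!r}: unknown format {fmt!r}")
    if kind == "numeric" and len(track.data):
        values = pd.to_numeric(track.data["value"], errors="coerce")
        if values.isna().any():
            raise TrackError(f"track {name!r}: non-numeric values in a numeric track")
        if not np.isfinite(values).all():
            raise TrackError(f"track {name!r}: non-finite values")
        track.data["value"] = values.astype(float)
    if kind == "categorical" and len(track.data):
        track.levels = tuple(sorted(track.data["value"].astype(str).unique()))
    if track.skipped_out_of_range:
        logger.warning(
            "track %s: skipped %d out-of-range records",
            name,
            track.skipped_out_of_range,
        )
    return track


def _expand_intervals(
    rows: list[tuple[str, int, int, object]], genome: Genome | None
) -> tuple[pd.DataFrame, int]:
    """Expand 0-based half-open intervals to 1-based per-position records."""
    chroms: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    values: list[np.ndarray] = []
    skipped = 0
    for chrom, start, end, value in rows:
        if genome is not None:
            if chrom not in genome:
                skipped += 1
                continue
            n = genome.length(chrom)
            if start >= n:
                skipped += 1
                continue
            end = min(end, n)
        pos = np.arange(start + 1, end + 1, dtype=np.int64)
        chroms.append(np.full(len(pos), chrom, dtype=object))
        positions.append(pos)
        values.append(np.full(len(pos), value, dtype=object))
    if not positions:
        return pd.DataFrame(columns=POSITION_KEY + ["value"]), skipped
    df = pd.DataFrame(
        {
            "chrom": np.concatenate(chroms),
            "pos": np.concatenate(positions),
            "value": np.concatenate(values),
        }
    )
    # overlapping intervals: last record wins, deterministically
    df = df.drop_duplicates(subset=POSITION_KEY, keep="last").reset_index(drop=True)
    return df, skipped


def _load_wiggle(path, fmt, genome) -> tuple[pd.DataFrame, int]:
    rows: list[tuple[str, int, int, object]] = []
    mode = "bedgraph"
    chrom, step, span, pos = "", 1, 1, 1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            try:
                if fields[0] == "fixedStep":
                    kv = dict(f.split("=", 1) for f in fields[1:])
                    chrom = kv["chrom"]
                    pos = int(kv["start"])          # wig starts are 1-based
                    step = int(kv.get("step", 1))
                    span = int(kv.get("span", 1))
                    mode = "fixed"
                elif fields[0] == "variableStep":
                    kv = dict(f.split("=", 1) for f in fields[1:])
                    chrom = kv["chrom"]
                    span = int(kv.get("span", 1))
                    mode = "variable"
                elif mode == "fixed" and len(fields) == 1:
                    rows.append((chrom, pos - 1, pos - 1 + span, float(fields[0])))
                    pos += step
                elif mode == "variable" and len(fields) == 2:
                    p = int(fields[0])
                    rows.append((chrom, p - 1, p - 1 + span, float(fields[1])))
                elif len(fields) == 4:
                    rows.append(
                        (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                    )
                else:
                    raise ValueError("unrecognized record")
            except (ValueError, KeyError, IndexError) as exc:
                raise TrackError(f"{path}: line {lineno}: {exc}") from exc
    return _expand_intervals(rows, genome)


def _load_bed(path, genome) -> tuple[pd.DataFrame, int]:
    rows: list[tuple[str, int, int, object]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                value = fields[3] if len(fields) > 3 else "1"
            except (ValueError, IndexError) as exc:
                raise TrackError(f"{path}: line {lineno}: {exc}") from exc
            rows.append((chrom, start, end, value))
    return _expand_intervals(rows, genome)


def _load_variant_tsv(path, value_column, genome) -> tuple[pd.DataFrame, int]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df.columns = [c.lstrip("#") for c in df.columns]
    required = set(VARIANT_KEY) | {value_column}
    missing = required - set(df.columns)
    if missing:
        raise TrackError(f"{path}: missing columns {sorted(missing)}")
    out = df[VARIANT_KEY + [value_column]].rename(columns={value_column: "value"})
    skipped = 0
    if genome is not None:
        ok = pd.Series(True, index=out.index)
        for chrom, grp in out.groupby("chrom"):
            if chrom not in genome:
                ok.loc[grp.index] = False
            else:
                ok.loc[grp.index] = grp["pos"].between(1, genome.length(chrom))
        skipped = int((~ok).sum())
        out = out[ok].reset_index(drop=True)
    out["pos"] = out["pos"].astype(np.int64)
    return out, skipped


def _load_vcf_info(path, info_field) -> pd.DataFrame:
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            value = rec.info.get(info_field)
            if value is None:
                continue
            if isinstance(value, (tuple, list)):
                values = value
            else:
                values = [value] * len(rec.alts or ())
            for alt, v in zip(rec.alts or (), values):
                if alt is None or len(alt) != 1 or len(rec.ref or "") != 1:
                    continue
                records.append((rec.chrom, rec.pos, rec.ref, alt, v))
    return pd.DataFrame(records, columns=VARIANT_KEY + ["value"])
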