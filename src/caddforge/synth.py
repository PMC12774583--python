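"""Synthetic pipeline inputs with known ground truth.

Generates, under one seed: an i.i.d. reference genome; a diverged ancestor
serialized as a 3-row MAF (reference + ancestor + outgroup, with uncovered
spans and at least one minus-strand reference block); a population VCF with
a Beta-distributed allele-frequency spectrum; and class-conditional
annotation tracks with planted effect sizes, alongside a Monte-Carlo
estimate of the Bayes-optimal ROC-AUC of the planted generative model.

Defaults emulate the study conditions at desk scale: ~1% ancestor/reference
divergence with a 2:1 transition bias, 10% of the genome unaligned, a
U-shaped allele-frequency spectrum (genetic drift pushes alleles toward
loss or fixation), four Gaussian "conservation-like" numeric features and
one three-level "chromatin-state-like" categorical feature, with 10%
missingness on two of the numeric tracks.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy.stats import norm

from .genome import Genome
from .maf import AlignmentBlock, MafRow, revcomp, write_maf

BASES = "ACGT"


class SynthError(ValueError):
    pass


class NumericFeatureCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    beta: float                 # class-1 mean shift (class-0 mean is 0)
    sigma: float = 1.0          # shared within-class SD
    missing_fraction: float = Field(0.0, ge=0.0, le=1.0)
    fmt: str = "tsv"            # 'tsv' (per-variant) or 'bedgraph' (per-position)
    imputation: str = "indicator"
    fixed_value: float | None = None


class CategoricalFeatureCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str = "state"
    levels: list[str] = ["reg_active", "reg_weak", "background"]
    p_derived: list[float] = [0.2, 0.3, 0.5]
    p_simulated: list[float] = [0.45, 0.3, 0.25]
    missing_fraction: float = Field(0.0, ge=0.0, le=1.0)


class SynthConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    genome_length: int = Field(1_000_000, ge=1)
    n_chroms: int = Field(1, ge=1)
    composition: list[float] = [0.25, 0.25, 0.25, 0.25]
    divergence: float = Field(0.01, ge=0.0, lt=1.0)
    transition_bias: float = Field(2.0, gt=0.0)
    unaligned_fraction: float = Field(0.1, ge=0.0, lt=1.0)
    n_blocks: int = Field(4, ge=1)
    ref_species: str = "refsp"
    ancestor_label: str = "Anc0"
    outgroup_label: str = "outg"
    n_pop_sites: int = Field(2000, ge=0)
    beta_a: float = Field(0.5, gt=0.0)
    beta_b: float = Field(0.5, gt=0.0)
    numeric_features: list[NumericFeatureCfg] = [
        NumericFeatureCfg(name="cons_a", beta=1.0, sigma=1.0, fmt="bedgraph"),
        NumericFeatureCfg(
            name="cons_b", beta=0.8, sigma=1.0, missing_fraction=0.1,
            imputation="mean_from_simulated",
        ),
        NumericFeatureCfg(name="cons_c", beta=0.5, sigma=1.0, missing_fraction=0.1),
        NumericFeatureCfg(
            name="cons_d", beta=0.3, sigma=1.0, imputation="fixed", fixed_value=0.0
        ),
    ]
    categorical_feature: CategoricalFeatureCfg | None = CategoricalFeatureCfg()
    oracle_draws: int = Field(1_000_000, ge=1000)


# -- substitution matrix ---------------------------------------------------

_TRANSITION = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def substitution_matrix(divergence: float, kappa: float) -> np.ndarray:
    """Per-site substitution probabilities Q[from, to]; rows sum to the
    divergence; transitions weighted ``kappa`` x transversions."""
    q = np.zeros((4, 4))
    for i, a in enumerate(BASES):
        weights = np.array(
            [
                0.0 if a == b else (kappa if (a, b) in _TRANSITION else 1.0)
                for b in BASES
            ]
        )
        q[i] = weights / weights.sum() * divergence
    return q


# -- generators ------------------------------------------------------------

def make_genome(cfg: SynthConfig, rng: np.random.Generator) -> Genome:
    comp = np.asarray(cfg.composition, dtype=float)
    if comp.shape != (4,) or comp.min() < 0 or not np.isclose(comp.sum(), 1.0):
        raise SynthError("composition must be 4 non-negative values summing to 1")
    if cfg.genome_length < 1:
        raise SynthError("genome_length must be >= 1")
    per = cfg.genome_length // cfg.n_chroms
    seqs = {}
    for i in range(cfg.n_chroms):
        n = per if i < cfg.n_chroms - 1 else cfg.genome_length - per * (cfg.n_chroms - 1)
        codes = rng.choice(4, size=n, p=comp)
        seqs[f"chr{i + 1}"] = "".join(np.array(list(BASES))[codes])
    return Genome(seqs)


def make_ancestor_and_maf(
    genome: Genome,
    cfg: SynthConfig,
    rng: np.random.Generator,
    maf_path: str | os.PathLike,
) -> pd.DataFrame:
    """Diverge an ancestor from the reference, write the MAF, return the
    truth table of planted differences (chrom, pos, anc, ref, covered)."""
    q = substitution_matrix(cfg.divergence, cfg.transition_bias)
    blocks: list[AlignmentBlock] = []
    truth_rows = []
    for chrom in genome:
        ref = genome[chrom]
        n = len(ref)
        ref_codes = np.frombuffer(ref.encode(), dtype=np.uint8)
        code = np.zeros(n, dtype=np.int64)
        for i, b in enumerate(BASES):
            code[ref_codes == ord(b)] = i
        mutate = rng.random(n) < cfg.divergence
        anc_codes = code.copy()
        idx = np.nonzero(mutate)[0]
        for i in idx:
            row = q[code[i]] / cfg.divergence
            anc_codes[i] = rng.choice(4, p=row)
        anc = "".join(np.array(list(BASES))[anc_codes])

        spans, covered_mask = _coverage_spans(n, cfg, rng)
        diff_idx = np.nonzero(anc_codes != code)[0]
        for i in diff_idx:
            truth_rows.append(
                {
                    "chrom": chrom,
                    "pos": int(i) + 1,
                    "anc": BASES[anc_codes[i]],
                    "ref": BASES[code[i]],
                    "covered": bool(covered_mask[i]),
                }
            )

        outg = _mutate_sequence(anc, cfg.divergence / 2, q, rng)
        for bi, (s, e) in enumerate(spans):
            minus = bi == 1 and len(spans) > 1  # exercise strand logic
            blocks.append(
                _make_block(cfg, chrom, n, s, e, ref[s:e], anc[s:e], outg[s:e], minus)
            )
    write_maf(blocks, maf_path)
    return pd.DataFrame(
        truth_rows, columns=["chrom", "pos", "anc", "ref", "covered"]
    )


def _coverage_spans(n, cfg, rng) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Split [0, n) into n_blocks covered spans separated by uncovered gaps
    totalling roughly unaligned_fraction of the chromosome."""
    n_gaps = cfg.n_blocks + 1
    gap_total = int(round(n * cfg.unaligned_fraction))
    if gap_total and n_gaps:
        cuts = np.sort(rng.integers(0, gap_total + 1, size=n_gaps - 1))
        gap_sizes = np.diff(np.concatenate(([0], cuts, [gap_total])))
    else:
        gap_sizes = np.zeros(n_gaps, dtype=int)
    covered_total = n - gap_total
    base = covered_total // cfg.n_blocks
    block_sizes = [base] * cfg.n_blocks
    block_sizes[-1] += covered_total - base * cfg.n_blocks
    spans = []
    pos = 0
    covered = np.zeros(n, dtype=bool)
    for g, b in zip(gap_sizes, block_sizes + [0]):
        pos += int(g)
        if b:
            spans.append((pos, pos + b))
            covered[pos : pos + b] = True
            pos += b
    return spans, covered


def _mutate_sequence(seq, rate, q, rng) -> str:
    codes = np.array([BASES.index(c) for c in seq], dtype=np.int64)
    idx = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in idx:
        row = q[codes[i]] / q[codes[i]].sum()
        codes[i] = rng.choice(4, p=row)
    return "".join(np.array(list(BASES))[codes])


def _make_block(cfg, chrom, src_size, s, e, ref_text, anc_text, outg_text, minus):
    size = e - s
    if minus:
        start = src_size - e
        rows = [
            MafRow(f"{cfg.ref_species}.{chrom}", start, size, "-", src_size, revcomp(ref_text)),
            MafRow(f"{cfg.ancestor_label}.{chrom}", start, size, "-", src_size, revcomp(anc_text)),
            MafRow(f"{cfg.outgroup_label}.{chrom}", start, size, "-", src_size, revcomp(outg_text)),
        ]
    else:
        rows = [
            MafRow(f"{cfg.ref_species}.{chrom}", s, size, "+", src_size, ref_text),
            MafRow(f"{cfg.ancestor_label}.{chrom}", s, size, "+", src_size, anc_text),
            MafRow(f"{cfg.outgroup_label}.{chrom}", s, size, "+", src_size, outg_text),
        ]
    return AlignmentBlock(tuple(rows))


def make_population_vcf(
    genome: Genome,
    cfg: SynthConfig,
    rng: np.random.Generator,
    path: str | os.PathLike,
) -> pd.DataFrame:
    """Place polymorphic sites uniformly, AF ~ Beta(a, b); returns the truth
    table (chrom, pos, ref, alt, af) and writes a decomposed biallelic VCF."""
    rows = []
    total = genome.total_length()
    weights = np.array([genome.length(c) / total for c in genome])
    chrom_names = list(genome)
    if cfg.n_pop_sites:
        chosen: set[tuple[str, int]] = set()
        chrom_idx = rng.choice(len(chrom_names), size=cfg.n_pop_sites, p=weights)
        for ci in chrom_idx:
            chrom = chrom_names[ci]
            pos = int(rng.integers(1, genome.length(chrom) + 1))
            if (chrom, pos) in chosen:
                continue
            chosen.add((chrom, pos))
            ref = genome.base(chrom, pos)
            if ref not in BASES:
                continue
            alt = rng.choice([b for b in BASES if b != ref])
            af = float(rng.beta(cfg.beta_a, cfg.beta_b))
            rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "af": af})
    truth = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "af"])
    if len(truth):
        truth = truth.sort_values(["chrom", "pos"], ignore_index=True)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        for chrom in genome:
            fh.write(f"##contig=<ID={chrom},length={genome.length(chrom)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in truth.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\tAF={r.af:.6f}\n")
    return truth


def make_tracks(
    variants: pd.DataFrame,
    cfg: SynthConfig,
    rng: np.random.Generator,
    out_dir: str | os.PathLike,
) -> dict:
    """Write class-conditional annotation tracks for labelled variants and
    the Monte-Carlo Bayes-AUC oracle of the planted generative model.

    ``variants`` needs columns chrom/pos/from/to/class. Numeric feature j of
    a class-y variant is Normal(y*beta_j, sigma_j); the categorical level is
    drawn from the class-conditional probabilities. A missing fraction per
    feature is withheld from the written tracks entirely.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    y = (variants["class"] == "simulated").to_numpy(dtype=int)
    n = len(variants)
    manifest: dict = {"tracks": [], "features": []}

    for feat in cfg.numeric_features:
        values = rng.normal(loc=y * feat.beta, scale=feat.sigma)
        present = rng.random(n) >= feat.missing_fraction
        df = variants[["chrom", "pos", "from", "to"]].copy()
        df["value"] = values
        df = df[present]
        if feat.fmt == "bedgraph":
            path = out_dir / f"{feat.name}.bedgraph"
            # per-position resolution: first variant at a position wins
            dfp = df.drop_duplicates(subset=["chrom", "pos"], keep="first")
            dfp = dfp.sort_values(["chrom", "pos"])
            with open(path, "w") as fh:
                for r in dfp.itertuples(index=False):
                    fh.write(f"{r.chrom}\t{r.pos - 1}\t{r.pos}\t{r.value:.6f}\n")
            manifest["tracks"].append(
                {"name": feat.name, "path": path.name, "format": "bedgraph", "kind": "numeric"}
            )
        else:
            path = out_dir / f"{feat.name}.tsv"
            df.to_csv(path, sep="\t", index=False, float_format="%.6f")
            manifest["tracks"].append(
                {"name": feat.name, "path": path.name, "format": "tsv", "kind": "numeric"}
            )
        manifest["features"].append(
            {
                "name": feat.name,
                "kind": "numeric",
                "beta": feat.beta,
                "sigma": feat.sigma,
                "imputation": feat.imputation,
                "fixed_value": feat.fixed_value,
            }
        )

    cat = cfg.categorical_feature
    if cat is not None:
        p0, p1 = np.asarray(cat.p_derived), np.asarray(cat.p_simulated)
        if not (np.isclose(p0.sum(), 1) and np.isclose(p1.sum(), 1)):
            raise SynthError("class-conditional level probabilities must sum to 1")
        levels = np.asarray(cat.levels, dtype=object)
        draws = np.where(
            y == 1,
            rng.choice(len(levels), size=n, p=p1 / p1.sum()),
            0,
        )
        # class-0 rows need their own distribution; redraw them
        idx0 = np.nonzero(y == 0)[0]
        draws[idx0] = rng.choice(len(levels), size=len(idx0), p=p0 / p0.sum())
        present = rng.random(n) >= cat.missing_fraction
        df = variants[["chrom", "pos", "from", "to"]].copy()
        df["value"] = levels[draws]
        df = df[present]
        path = out_dir / f"{cat.name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        manifest["tracks"].append(
            {"name": cat.name, "path": path.name, "format": "tsv", "kind": "categorical"}
        )
        manifest["features"].append(
            {"name": cat.name, "kind": "categorical", "levels": cat.levels}
        )

    oracle = bayes_auc_oracle(cfg, rng)
    manifest["bayes_auc"] = oracle
    with open(out_dir / "oracle.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")
    return manifest


# -- Bayes-AUC oracle ------------------------------------------------------

def gaussian_auc(beta: float, sigma: float) -> float:
    """Closed-form Bayes AUC for a single complete Gaussian feature with
    class means 0 and beta and shared SD sigma: Phi(beta / (sigma*sqrt(2)))."""
    return float(norm.cdf(abs(beta) / (sigma * np.sqrt(2.0))))


def bayes_auc_oracle(cfg: SynthConfig, rng: np.random.Generator) -> dict:
    """Monte-Carlo estimate of the Bayes-optimal ROC-AUC of the planted
    feature model, honouring per-feature missingness (a missing feature
    contributes nothing to the log-likelihood ratio)."""
    half = cfg.oracle_draws // 2
    n = 2 * half
    y = np.concatenate([np.zeros(half, dtype=int), np.ones(half, dtype=int)])
    llr = np.zeros(n)
    for feat in cfg.numeric_features:
        x = rng.normal(loc=y * feat.beta, scale=feat.sigma)
        observed = rng.random(n) >= feat.missing_fraction
        contrib = feat.beta * (x - feat.beta / 2.0) / feat.sigma**2
        llr += np.where(observed, contrib, 0.0)
    cat = cfg.categorical_feature
    if cat is not None:
        p0, p1 = np.asarray(cat.p_derived, float), np.asarray(cat.p_simulated, float)
        p0, p1 = p0 / p0.sum(), p1 / p1.sum()
        lvl = np.empty(n, dtype=int)
        lvl[y == 0] = rng.choice(len(p0), size=half, p=p0)
        lvl[y == 1] = rng.choice(len(p1), size=half, p=p1)
        observed = rng.random(n) >= cat.missing_fraction
        with np.errstate(divide="ignore"):
            table = np.log(p1) - np.log(p0)
        llr += np.where(observed, table[lvl], 0.0)
    # rank-based AUC with tie correction
    from scipy.stats import rankdata

    ranks = rankdata(llr)
    auc = (ranks[y == 1].sum() - half * (half + 1) / 2) / (half * half)
    return {"value": float(auc), "n_draws": n}


def generate_inputs(cfg: SynthConfig, out_dir: str | os.PathLike) -> dict:
    """Write genome FASTA, MAF and population VCF plus truth tables; track
    generation happens later, once labelled variant sets exist."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genome = make_genome(cfg, rng)
    genome.to_fasta(out_dir / "ref.fa")
    truth_div = make_ancestor_and_maf(genome, cfg, rng, out_dir / "alignment.maf")
    truth_div.to_csv(out_dir / "truth_divergence.tsv", sep="\t", index=False)
    truth_pop = make_population_vcf(genome, cfg, rng, out_dir / "population.vcf")
    truth_pop.to_csv(out_dir / "truth_population.tsv", sep="\t", index=False)
    return {
        "ref": str(out_dir / "ref.fa"),
        "maf": str(out_dir / "alignment.maf"),
        "vcf": str(out_dir / "population.vcf"),
        "n_planted_differences": int(len(truth_div)),
        "n_pop_sites": int(len(truth_pop)),
    }
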