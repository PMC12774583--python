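"""Dependency-ordered stage runner.

Stages: ancestor -> derive / rates -> simulate [-> synth_tracks]
-> annotate -> train / validate -> score. Each stage writes its artifacts
plus a JSON manifest (input checksums, parameters, seed, output checksums);
a rerun with unchanged inputs and parameters is skipped unless forced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .ancestor import AncestorMap, build_ancestor_map, coverage_stats
from .config import PipelineConfig
from .consequence import GeneModels
from .features import (
    FeatureSpec,
    assemble_features,
    encode_and_impute,
    load_feature_matrix,
    load_imputation_stats,
    save_feature_matrix,
    save_imputation_stats,
    variants_frame,
)
from .genome import Genome
from .maf import parse_maf
from .model import TrainedModel, cross_validate, subset_auc, top_features, train
from .rates import MutationRateModel, estimate_mutation_rates, simulate_variants
from .scoring import score_variants, write_scores
from .synth import make_tracks
from .tracks import load_track
from .variants import (
    call_derived_variants,
    load_population_vcf,
    read_snv_tsv,
    write_snv_tsv,
    write_snv_vcf,
)

logger = logging.getLogger(__name__)

STAGE_ORDER = [
    "ancestor",
    "derive",
    "rates",
    "simulate",
    "synth_tracks",
    "annotate",
    "train",
    "validate",
    "score",
]

STAGE_DEPS = {
    "ancestor": [],
    "derive": ["ancestor"],
    "rates": ["ancestor"],
    "simulate": ["derive", "rates"],
    "synth_tracks": ["derive", "simulate"],
    "annotate": ["derive", "simulate"],
    "train": ["annotate"],
    "validate": ["annotate"],
    "score": ["train"],
}


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.out = Path(cfg.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._genome: Genome | None = None
        self._anc: AncestorMap | None = None
        self._pop = None
        self._gene_models: GeneModels | None = None

    # -- shared lazily loaded inputs --------------------------------------

    @property
    def genome(self) -> Genome:
        if self._genome is None:
            self._genome = Genome.from_fasta(self.cfg.reference)
        return self._genome

    @property
    def ancestor_map(self) -> AncestorMap:
        if self._anc is None:
            path = self.out / "ancestor.tsv"
            if not path.exists():
                raise PipelineError("ancestor.tsv missing: run the 'ancestor' stage first")
            self._anc = AncestorMap.from_tsv(
                path, {c: self.genome.length(c) for c in self.genome}
            )
        return self._anc

    @property
    def population(self):
        if self._pop is None and self.cfg.population_vcf is not None:
            self._pop = load_population_vcf(self.cfg.population_vcf)
        return self._pop

    @property
    def gene_models(self) -> GeneModels | None:
        if self._gene_models is None and self.cfg.gff is not None:
            self._gene_models = GeneModels.from_gff3(self.cfg.gff)
        return self._gene_models

    # -- track / feature-spec resolution ----------------------------------

    def _synth_manifest(self) -> dict | None:
        path = self.out / "tracks" / "oracle.json"
        if self.cfg.synthetic_tracks is not None and path.exists():
            with open(path) as fh:
                return json.load(fh)
        return None

    def track_defs(self) -> list[dict]:
        defs = [
            {
                "name": t.name,
                "path": t.path,
                "format": t.format,
                "kind": t.kind,
                "value_column": t.value_column,
                "info_field": t.info_field,
            }
            for t in self.cfg.tracks
        ]
        manifest = self._synth_manifest()
        if manifest:
            for t in manifest["tracks"]:
                defs.append(
                    {
                        "name": t["name"],
                        "path": str(self.out / "tracks" / t["path"]),
                        "format": t["format"],
                        "kind": t["kind"],
                        "value_column": "value",
                        "info_field": None,
                    }
                )
        return defs

    def load_tracks(self) -> dict:
        tracks = {}
        for d in self.track_defs():
            tracks[d["name"]] = load_track(
                d["path"],
                d["format"],
                d["name"],
                d["kind"],
                genome=self.genome,
                value_column=d["value_column"],
                info_field=d["info_field"],
            )
        return tracks

    def feature_specs(self) -> list[FeatureSpec]:
        specs = [
            FeatureSpec(
                name=f.name,
                source=f.source,
                kind=f.kind,
                imputation=f.imputation,
                fixed_value=f.fixed_value,
                levels=tuple(f.levels),
            )
            for f in self.cfg.features
        ]
        manifest = self._synth_manifest()
        if manifest:
            for f in manifest["features"]:
                if f["kind"] == "numeric":
                    specs.append(
                        FeatureSpec(
                            name=f["name"],
                            source=f["name"],
                            kind="numeric",
                            imputation=f.get("imputation", "indicator"),
                            fixed_value=f.get("fixed_value"),
                        )
                    )
                else:
                    specs.append(
                        FeatureSpec(
                            name=f["name"],
                            source=f["name"],
                            kind="categorical",
                            levels=tuple(f["levels"]),
                        )
                    )
        return specs

    # -- manifest bookkeeping ----------------------------------------------

    def _manifest_path(self, stage: str) -> Path:
        return self.out / f"{stage}.manifest.json"

    def _stage_inputs(self, stage: str) -> list[Path]:
        cfg = self.cfg
        inputs = {
            "ancestor": [cfg.reference, cfg.maf],
            "derive": [cfg.reference, self.out / "ancestor.tsv"],
            "rates": [cfg.reference, self.out / "ancestor.tsv"],
            "simulate": [
                cfg.reference,
                self.out / "ancestor.tsv",
                self.out / "derived.tsv",
                self.out / "rates.json",
            ],
            "synth_tracks": [self.out / "derived.tsv", self.out / "simulated.tsv"],
            "annotate": [
                cfg.reference,
                self.out / "derived.tsv",
                self.out / "simulated.tsv",
            ],
            "train": [self.out / "features.tsv", self.out / "imputation_stats.json"],
            "validate": [self.out / "features.tsv", self.out / "imputation_stats.json"],
            "score": [cfg.reference, self.out / "model.json"],
        }[stage]
        paths = [Path(p) for p in inputs]
        if stage in ("derive", "simulate") and cfg.population_vcf:
            paths.append(Path(cfg.population_vcf))
        if stage in ("annotate", "score"):
            paths.extend(Path(d["path"]) for d in self.track_defs())
            if cfg.gff:
                paths.append(Path(cfg.gff))
        return paths

    def _should_skip(self, stage: str, params: dict) -> bool:
        mpath = self._manifest_path(stage)
        if not mpath.exists():
            return False
        try:
            with open(mpath) as fh:
                old = json.load(fh)
        except json.JSONDecodeError:
            return False
        if old.get("params") != params:
            return False
        inputs = {str(p): _sha256(p) for p in self._stage_inputs(stage) if p.exists()}
        if old.get("inputs") != inputs:
            return False
        for path, digest in old.get("outputs", {}).items():
            p = Path(path)
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    def _write_manifest(self, stage: str, params: dict, outputs: list[Path]) -> None:
        manifest = {
            "stage": stage,
            "seed": self.cfg.seed,
            "params": params,
            "inputs": {str(p): _sha256(p) for p in self._stage_inputs(stage) if p.exists()},
            "outputs": {str(p): _sha256(p) for p in outputs},
        }
        with open(self._manifest_path(stage), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")

    # -- stages -------------------------------------------------------------

    def stage_ancestor(self) -> list[Path]:
        cfg = self.cfg
        blocks = parse_maf(cfg.maf)
        amap = build_ancestor_map(
            blocks,
            self.genome,
            cfg.ref_species,
            ancestor_label=cfg.ancestor_label,
            outgroup_labels=cfg.outgroup_labels,
            strategy=cfg.consensus_strategy,
        )
        self._anc = amap
        out_tsv = self.out / "ancestor.tsv"
        amap.to_tsv(out_tsv)
        cov = coverage_stats(amap, self.genome)
        cov_path = self.out / "ancestor_coverage.tsv"
        with open(cov_path, "w") as fh:
            fh.write("#chrom\tcovered_fraction\n")
            for chrom, frac in cov.items():
                fh.write(f"{chrom}\t{frac:.6f}\n")
        return [out_tsv, cov_path]

    def stage_derive(self) -> list[Path]:
        snvs = call_derived_variants(
            self.genome, self.ancestor_map, self.population, self.cfg.af_fixed
        )
        tsv = self.out / "derived.tsv"
        write_snv_tsv(snvs, tsv)
        vcf = self.out / "derived.vcf"
        write_snv_vcf(snvs, self.genome, vcf)
        return [tsv, vcf]

    def stage_rates(self) -> list[Path]:
        model = estimate_mutation_rates(
            self.genome,
            self.ancestor_map,
            self.cfg.window_size,
            self.cfg.min_window_bases,
        )
        path = self.out / "rates.json"
        model.to_json(path)
        return [path]

    def stage_simulate(self) -> list[Path]:
        derived = read_snv_tsv(self.out / "derived.tsv")
        model = MutationRateModel.from_json(self.out / "rates.json")
        snvs = simulate_variants(
            model,
            self.genome,
            self.ancestor_map,
            n_target=len(derived),
            pop=self.population,
            af_exclude=self.cfg.af_exclude,
            seed=self.cfg.seed,
            exclude={v.key for v in derived},
        )
        tsv = self.out / "simulated.tsv"
        write_snv_tsv(snvs, tsv)
        vcf = self.out / "simulated.vcf"
        write_snv_vcf(snvs, self.genome, vcf)
        return [tsv, vcf]

    def stage_synth_tracks(self) -> list[Path]:
        scfg = self.cfg.synthetic_tracks
        if scfg is None:
            raise PipelineError("synth_tracks stage needs a synthetic_tracks config section")
        variants = self._combined_variants()
        rng = np.random.default_rng([self.cfg.seed, 7])
        tdir = self.out / "tracks"
        make_tracks(variants, scfg, rng, tdir)
        return sorted(tdir.iterdir())

    def _combined_variants(self) -> pd.DataFrame:
        derived = read_snv_tsv(self.out / "derived.tsv")
        simulated = read_snv_tsv(self.out / "simulated.tsv")
        return variants_frame(derived + simulated)

    def stage_annotate(self) -> list[Path]:
        keys = self._combined_variants()
        specs = self.feature_specs()
        tracks = self.load_tracks()
        records = assemble_features(
            keys[["chrom", "pos", "from", "to"]],
            specs,
            tracks,
            self.genome,
            self.cfg.context_window,
            self.gene_models,
        )
        labels = (keys["class"] == "simulated").to_numpy(dtype=int)
        fm = encode_and_impute(records, specs, labels, row_keys=keys)
        fpath = self.out / "features.tsv"
        save_feature_matrix(fm, fpath)
        spath = self.out / "imputation_stats.json"
        save_imputation_stats(fm.imputation_stats, spath)
        return [fpath, spath]

    def stage_train(self) -> list[Path]:
        stats = load_imputation_stats(self.out / "imputation_stats.json")
        fm = load_feature_matrix(self.out / "features.tsv", stats)
        model = train(
            fm,
            l2=self.cfg.model.l2,
            max_iter=self.cfg.model.max_iter,
            standardize=self.cfg.model.standardize,
        )
        mpath = self.out / "model.json"
        model.to_json(mpath)
        tpath = self.out / "top_features.tsv"
        with open(tpath, "w") as fh:
            fh.write("#feature\tweight\n")
            for name, w in top_features(model, k=10):
                fh.write(f"{name}\t{w:.6g}\n")
        return [mpath, tpath]

    def stage_validate(self) -> list[Path]:
        stats = load_imputation_stats(self.out / "imputation_stats.json")
        fm = load_feature_matrix(self.out / "features.tsv", stats)
        report = cross_validate(
            fm,
            k=self.cfg.cv_folds,
            seed=self.cfg.seed,
            l2=self.cfg.model.l2,
            max_iter=self.cfg.model.max_iter,
            standardize=self.cfg.model.standardize,
        )
        cpath = self.out / "cv_report.tsv"
        report.to_tsv(cpath)
        spath = self.out / "subset_auc.tsv"
        subsets = self._subset_masks(fm)
        table = subset_auc(fm.y, report.oof_scores, subsets)
        table.to_csv(spath, sep="\t", index=False, float_format="%.6f")
        return [cpath, spath]

    def _subset_masks(self, fm) -> dict[str, np.ndarray]:
        masks: dict[str, np.ndarray] = {"all": np.ones(fm.X.shape[0], dtype=bool)}
        defs = dict(self.cfg.subsets)
        manifest = self._synth_manifest()
        if not defs and manifest:
            # default subset report: one subset per planted categorical level
            for f in manifest["features"]:
                if f["kind"] == "categorical":
                    for lvl in f["levels"]:
                        col = f"{f['name']}={lvl}"
                        if col in fm.column_names:
                            j = fm.column_names.index(col)
                            masks[lvl] = fm.X[:, j] == 1.0
        for name, sub in defs.items():
            mask = np.zeros(fm.X.shape[0], dtype=bool)
            for value in sub.values:
                col = f"{sub.feature}={value}"
                if col not in fm.column_names:
                    raise PipelineError(
                        f"subset {name!r}: encoded column {col!r} not found"
                    )
                mask |= fm.X[:, fm.column_names.index(col)] == 1.0
            masks[name] = mask
        return masks

    def stage_score(self) -> list[Path]:
        model = TrainedModel.from_json(self.out / "model.json")
        specs = self.feature_specs()
        tracks = self.load_tracks()
        table = score_variants(
            self.genome,
            model,
            specs,
            tracks,
            region=self.cfg.parsed_region(),
            context_window=self.cfg.context_window,
            gene_models=self.gene_models,
            chunk_size=self.cfg.chunk_size,
        )
        path = self.out / "scores.tsv"
        write_scores(table, path)
        return [path]

    # -- driver -------------------------------------------------------------

    def run(self, stages: list[str] | None = None, force: bool = False) -> dict[str, list[Path]]:
        requested = list(STAGE_ORDER) if stages is None else list(stages)
        for s in requested:
            if s not in STAGE_ORDER:
                raise PipelineError(f"unknown stage {s!r}")
        if self.cfg.synthetic_tracks is None:
            requested = [s for s in requested if s != "synth_tracks"]
        elif stages is None:
            pass  # full run keeps synth_tracks in order
        requested.sort(key=STAGE_ORDER.index)

        params = self.cfg.model_dump(mode="json")
        done: dict[str, list[Path]] = {}
        for stage in requested:
            deps = list(STAGE_DEPS[stage])
            if stage in ("annotate", "score") and self.cfg.synthetic_tracks is not None:
                deps.append("synth_tracks")
            for dep in deps:
                if dep in done:
                    continue
                marker = self._dep_marker(dep)
                if not marker.exists():
                    raise PipelineError(
                        f"stage {stage!r} needs {marker.name} — run the {dep!r} stage first"
                    )
            if not force and self._should_skip(stage, params):
                logger.info("stage %s: up to date, skipped", stage)
                done[stage] = []
                continue
            t0 = time.monotonic()
            outputs = getattr(self, f"stage_{stage}")()
            self._write_manifest(stage, params, outputs)
            logger.info("stage %s: %.2fs", stage, time.monotonic() - t0)
            done[stage] = outputs
        return done

    def _dep_marker(self, dep: str) -> Path:
        return {
            "ancestor": self.out / "ancestor.tsv",
            "derive": self.out / "derived.tsv",
            "rates": self.out / "rates.json",
            "simulate": self.out / "simulated.tsv",
            "synth_tracks": self.out / "tracks" / "oracle.json",
            "annotate": self.out / "features.tsv",
            "train": self.out / "model.json",
            "validate": self.out / "cv_report.tsv",
        }[dep]


def run_pipeline(
    cfg: PipelineConfig, stages: list[str] | None = None, force: bool = False
) -> dict[str, list[Path]]:
    """Run the requested stages (all, in dependency order, when None)."""
    return PipelineRun(cfg).run(stages, force=force)
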