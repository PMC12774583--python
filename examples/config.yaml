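# Full pipeline configuration schema with defaults.
#
# Paths are resolved relative to this file. Run with:
#   caddforge all --config config.yaml

reference: fixtures/ref.fa          # reference genome FASTA
maf: fixtures/alignment.maf         # multiple alignment with ancestor rows
ref_species: refsp                  # species prefix of reference rows in the MAF
ancestor_label: Anc0                # ancestor row prefix (Cactus-style)
# ... or instead of ancestor_label, consensus over outgroups:
# outgroup_labels: [outg1, outg2]
# consensus_strategy: strict_consensus   # or: majority

population_vcf: fixtures/population.vcf  # optional; AF from INFO/AF or AC/AN
# gff: genes.gff3                   # optional; enables the built-in
                                    # consequence + Grantham features

out_dir: run

af_fixed: 0.9        # derived variants need reference-allele AF above this
af_exclude: 0.1      # simulated candidates seen above this AF are excluded
window_size: 100000  # mutation-rate window (bp)
min_window_bases: 1000   # sparse windows fall back to genome-wide rates
context_window: 75   # half-width for GC/CpG sequence-context features

# Annotation sources. Formats: bedgraph | wig | bed | tsv | vcf-info.
tracks:
  - name: phylop
    path: tracks/phylop.bedgraph
    format: bedgraph
    kind: numeric
  - name: chromatin
    path: tracks/states.bed
    format: bed
    kind: categorical
  - name: vep_csq
    path: tracks/consequences.tsv   # columns: chrom pos from to value
    format: tsv
    kind: categorical
    value_column: value

# Feature specs: source is a track name or one of the builtins
# gc_fraction / cpg_count / ref_base / consequence / grantham.
# Imputation: indicator | mean_from_simulated | fixed (categoricals:
# indicator only).
features:
  - {name: phylop, source: phylop, kind: numeric, imputation: mean_from_simulated}
  - {name: gc, source: gc_fraction, kind: numeric, imputation: indicator}
  - {name: cpg, source: cpg_count, kind: numeric, imputation: fixed, fixed_value: 0.0}
  - {name: refbase, source: ref_base, kind: categorical, levels: [A, C, G, T]}
  - name: chromatin
    source: chromatin
    kind: categorical
    levels: [enhancer, promoter, quiescent]
  - name: csq
    source: vep_csq
    kind: categorical
    levels: [intergenic, intronic, splice_site, exonic, synonymous, missense, stop_gained]

model:
  l2: 0.1            # inverse-regularization constant C of the logistic fit
  max_iter: 100
  standardize: false

cv_folds: 5

# Fig-2-style subset AUC report: predicates over categorical feature levels.
subsets:
  coding:     {feature: csq, values: [synonymous, missense, stop_gained]}
  missense:   {feature: csq, values: [missense]}
  synonymous: {feature: csq, values: [synonymous]}
  stop_gained: {feature: csq, values: [stop_gained]}
  splice:     {feature: csq, values: [splice_site]}
  intronic:   {feature: csq, values: [intronic]}
  intergenic: {feature: csq, values: [intergenic]}

# region: chr1:1-100000   # optional scoring restriction (N is region-local)
chunk_size: 200000         # scoring chunk, positions per batch
seed: 1
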