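# Methods

## Ancestral-allele projection

The pipeline reads a multiple alignment (MAF) and projects an ancestral
allele onto every reference position. Two modes are supported: an explicit
ancestor row (as Progressive Cactus emits after `hal2maf`), and a consensus
over named outgroup rows for Compara-style exports that carry no ancestor
sequences. Consensus is either `strict_consensus` (a base is recorded only
when all outgroups agree; disagreement or gaps leave the site unaligned) or
`majority` (modal base; exact ties are marked AMBIGUOUS).

Coordinates are 1-based inclusive internally; MAF's 0-based half-open,
strand-relative convention is converted at the parser boundary. For a
minus-strand reference row the forward start is `srcSize − start − size`,
text columns map to descending forward positions, and column characters are
complemented. Each position ends in exactly one state:

* a concrete base `A/C/G/T`;
* `UNALIGNED` (`.`) — covered by no block, or the ancestor carries a gap or
  non-ACGT character there;
* `AMBIGUOUS` (`?`) — overlapping blocks assign conflicting values.

Conflict resolution is deliberately conservative: any two different
explicit assignments (base vs different base, or base vs explicit gap)
yield AMBIGUOUS rather than first-wins, making the map independent of block
order. Only concrete positions feed the variant sets, so both sentinels act
as exclusions downstream.

## Variant sets

**Derived (proxy-neutral).** One SNV per aligned position where ancestor
and reference bases are both concrete and differ; `from` is the ancestral
base, `to` the reference base. When a population VCF is supplied, the
reference (derived) allele frequency is computed as 1 − Σ alternate AFs at
the position (multiallelic records decomposed per alternate; AF from
INFO/AF, falling back to AC/AN) and the variant is kept only when it
exceeds `af_fixed` (default 0.9). Positions absent from the VCF are treated
as fixed. The 90% rule is applied to the derived allele's own frequency;
`af_fixed` is configurable for the alternative "any allele" reading.

**Mutation-rate model.** Among aligned sites, windows of `window_size`
(default 100 kb — "local" without being so small that counts are noisy)
accumulate a 4×4 ancestor→reference substitution count matrix and
per-ancestral-base exposure counts; the rate is their ratio. Windows with
fewer than `min_window_bases` (default 1000) aligned bases fall back to the
genome-wide matrix. Only the single reference/ancestor contrast is used —
no CpG-context-specific rates and no multi-ancestor ladder.

**Simulated (proxy-deleterious).** Candidates are all (aligned position,
alternate allele) pairs, weighted by their window's rate for that
substitution type anchored on the reference base. Excluded are candidates
whose allele appears in the population above `af_exclude` (default 0.1) and
candidates colliding with a derived (position, allele) pair — the latter
prevents the same substitution carrying both class labels. Sampling is
without replacement via Gumbel-perturbed log-weights (top-n keys), so the
draw is an exact weighted sample and a deterministic function of the seed.
The pipeline always requests exactly as many simulated as derived variants;
a candidate pool smaller than the target is a hard error reporting the pool
size. Because sampling is without replacement, empirical substitution-type
frequencies match the normalized rates only while the number of draws is
small relative to each type's pool; the rate-recovery experiment therefore
draws 100,000 from an 8 Mb single-window fixture (<1% depletion per type).

## Annotation and encoding

Tracks come in four formats: bedGraph/wig and BED (0-based half-open,
expanded to per-position lookups; overlaps resolve to the last record),
per-variant TSV keyed on (chrom, pos, from, to), and VCF INFO fields.
Built-in features: GC fraction and CpG count in a ±`context_window`
(default 75 bp, standard CADD practice) window clipped at chromosome ends
(GC denominator counts non-N bases; an all-N window is missing), the
reference base, and — when a GFF3 is supplied — a minimal consequence
caller (intergenic / intronic / splice_site within 2 bp of an exon
boundary / exonic / synonymous / missense / stop_gained, most severe across
transcripts) plus Grantham distances, attached to missense calls only. The
bundled Grantham table is the published 20×20 physicochemical distance
matrix. Rich consequence sets from an external annotator can be supplied as
a per-variant TSV track instead; computing alignments, VEP, SIFT, GERP or
phyloP themselves is out of scope — they are consumed as pre-made tracks.

Encoding is a pure function of the feature specs: numeric features
contribute one column (plus a 0/1 missing-indicator column when imputation
is `indicator`); categoricals contribute one column per declared level plus
an indicator column, with unknown levels at scoring time mapping to
all-zero one-hot + indicator 1. Missing numerics are filled per spec with
0 + indicator, a fixed constant, or the mean over **simulated-class rows
only** (`mean_from_simulated`, mirroring imputation from the genome-wide
simulated background). Simulated-class means are computed once at training
time and stored in the model artifact; scoring reuses them and never
recomputes statistics from the scored variants. Means are stored for every
`mean_from_simulated` feature — even ones with no missing training cells —
so scoring-time gaps are always fillable. Categorical features support
indicator handling only: a mean of one-hot columns has no useful reading.

## Model and validation

The classifier is scikit-learn's logistic regression (lbfgs, deterministic,
tolerance 1e-4) with class 1 = simulated. The "L2 penalization 0.1" setting
is interpreted in that implementation's parameterization, i.e. `C = 0.1`
(a strong penalty); both `C` and `max_iter` (default 100) are config knobs
recorded in the model metadata. Features enter unstandardized by default —
the penalty acts on raw encoded columns; `standardize: true` switches to
per-fold z-scoring, and the choice is recorded in the artifact rather than
guessed silently.

ROC-AUC is the Mann–Whitney statistic (ties at half credit). Validation
uses stratified k-fold CV (default k = 5); stratification keeps both
classes in every fold even on small synthetic runs. Subset AUCs are
computed on out-of-fold predictions restricted to configured predicates
over categorical annotation levels; subsets missing a class are reported
undefined with their counts. `top_features` ranks weights by magnitude
with column-order tie-breaking.

## Scoring

Every position with a concrete reference base yields its three alternate
alleles in fixed A<C<G<T order; N bases are skipped. The raw score is the
linear predictor `wᵀx + b` — monotone-equivalent to the class-1
probability, hence rank-identical and cheaper. PHRED scaling assigns
`−10·log₁₀(i/N)` with rank 1 = highest raw score; tied raw scores share the
minimum rank of their tie group, so equal evidence yields equal scores and
the minimum PHRED is exactly 0. Ranking is global over the scored set
(whole genome, or an explicit region whose label and N are written into
the output header). Output is a coordinate-sorted TSV (PHRED to three
decimals) suitable for bgzip/tabix.

## Synthetic fixtures

The generator emulates the pipeline's study conditions at desk scale, all
under one seed: an i.i.d. uniform-composition genome; an ancestor diverged
at 1% per site with a 2:1 transition:transversion bias; 10% of each
chromosome left unaligned; a 3-row MAF (reference + ancestor + outgroup)
with at least one minus-strand reference block; 2000 polymorphic sites with
a U-shaped Beta(0.5, 0.5) allele-frequency spectrum (drift pushes alleles
toward loss or fixation, giving both the >90% and >10% filters something to
act on); four Gaussian "conservation-like" numeric features with class-1
mean shifts (1.0, 0.8, 0.5, 0.3), unit SD and 10% missingness on two of
them, exercising all three imputation paths; and one three-level
"chromatin-state-like" categorical feature with class-conditional level
probabilities. One numeric feature is serialized as a per-position bedGraph
(first variant at a position wins on the rare same-position collision), the
rest as per-variant TSVs.

Alongside the tracks the generator emits a Monte-Carlo estimate (10⁶ draws)
of the Bayes-optimal ROC-AUC of the planted model: per draw, the
log-likelihood ratio sums each **observed** feature's contribution
(Gaussian: β(x − β/2)/σ²; categorical: log p₁/p₀) and missing features
contribute nothing — exactly the family an indicator-imputed linear
logistic model can represent, so the cross-validated AUC of the trained
pipeline should match the oracle up to sampling error. For a single
complete Gaussian feature the closed form Φ(β/(σ√2)) cross-checks the
Monte-Carlo estimate. The end-to-end comparison uses exactly the planted
features (no sequence-context builtins) so the oracle is the correct
target; context builtins would add small class-correlated signal from the
rate-weighted placement of simulated variants that the oracle does not
model.

What the fixtures do **not** emulate: phylogenetically realistic
divergence (no rate heterogeneity, no indels inside blocks), linkage and
recombination in the population sites, selection, and annotation tracks
with spatial autocorrelation. Passing tests therefore demonstrate the
pipeline machinery — coordinate handling, filtering rules, balanced-set
construction, encoding/imputation provenance, rank transformation,
determinism — not that real-genome AUCs of any particular magnitude will
be achieved.

## Orchestration and reproducibility

Stages run in dependency order (ancestor → derive/rates → simulate
[→ synth_tracks] → annotate → train/validate → score) under a plain
internal runner; each stage writes a manifest with input checksums,
parameters and output checksums, and is skipped on rerun while those are
unchanged. In self-contained synthetic runs, track generation is itself a
stage between simulate and annotate, because planted effects are
class-conditional and need the labelled variant sets to exist. All
randomness (simulation draw, fold assignment, fixture generation) derives
from the config seed; two runs with identical config and inputs produce
byte-identical variant sets, matrices, models and score tables.

Problem sizes used by the shipped verification runs: the end-to-end study
uses a 1 Mb genome (≈18,000 training variants, 3,000,000 scored SNVs), the
rate-recovery experiment an 8 Mb single-window fixture with 100,000 draws,
and the determinism check two full runs at 100 kb.

## Known limitations

* SNVs only — no indels or structural variants, by design.
* The consequence caller assumes well-formed gene models with complete
  codons (phase-0 first CDS); partial trailing codons fall back to
  `exonic`; stop-loss is reported as missense.
* Interval tracks are expanded per position in memory, which is intended
  for desk-scale and per-chromosome use rather than multi-gigabase genomes
  in one pass.
* Scoring-time annotations for positions outside any track are imputed;
  in sparse-track settings large tie groups of identically imputed SNVs
  share one PHRED value.
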