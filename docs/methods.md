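# Methods

## The filtering model

`fvc` treats post-calling quality control as supervised binary
classification. Each variant call is a 20-dimensional feature vector; the
label is whether the call matches a gold-standard truth set. The
classifier is an XGBoost gradient-boosted tree ensemble with the
`binary:logistic` objective, so its output is directly the probability
that the call is a true variant. Two modelling commitments follow the
filtering problem rather than generic ML practice:

* **Imbalance is signal.** Real germline call sets are dominated by true
  calls (ratios of thousands to one occur). Training data is used exactly
  as assembled — no resampling, reweighting or `scale_pos_weight`
  anywhere. The learned probabilities therefore inherit the base rate of
  the pipeline they were trained on, which is also why a model should be
  applied to calls from the same caller pipeline it was trained on
  (`score_batch` warns on a declared mismatch but does not refuse).
* **Missingness is explicit.** Annotations that are undefined for a call
  (rank-sum tests with no alt reads, MBQ with no alt support) are NaN and
  passed to the booster natively, which learns a branch direction for
  them. Nothing is zero-filled.

A call is `FILTERED` iff its probability is strictly below the threshold
(default 0.5); a score exactly at the threshold is retained. SNVs and
INDELs share one model, with the variant type as a feature; evaluating
them separately is a reporting split, not a model split.

### Booster parameters

Library-default XGBoost hyperparameters are used (`tree_method=hist`,
100 boosting rounds, `nthread=1` for bit-stable runs), with every
parameter overridable through `train(params=...)` / `fvc train --params`
and recorded in the model bundle's metadata together with the seed and
class counts. No hyperparameter search is built in: on separable data
the defaults are far from the binding constraint, and a search would
entangle evaluation with tuning.

## The feature schema

20 features in three categories; the schema is carried as data (ordered
names + category tags) in feature tables and model bundles, so an
alternative feature set is a schema substitution, not a code change.

| category | features | notes |
|---|---|---|
| sequence (4) | VARTYPE, GC_CONTENT, HOMOPOLYMER_RUN, REPEAT_UNITS | computed from a ±50 bp reference window; 50 bp captures homopolymer/repeat context at read scale |
| experiment (8) | DP, AD_ALT, VAF, MBQ_ALT, MMQ, MQ0_FRAC, STRAND_BALANCE, MEDIAN_READPOS_ALT | pileup summaries over QC-passing reads (duplicate/secondary/supplementary/QC-fail excluded) |
| analysis (8) | QUAL, QD, GQ, FS, SOR, MQ_RANKSUM, READPOS_RANKSUM, BASEQ_RANKSUM | caller annotations, recomputed natively from the pileup when absent |

Precedence: a value present in the caller's INFO/FORMAT wins over the
native recomputation, honoring caller provenance; the native path exists
so that callers that emit few annotations (e.g. DeepVariant) still yield
complete vectors. The native recomputations are:

* **FS** — phred-scaled two-sided Fisher exact p on the ref/alt ×
  forward/reverse table; 0 for any empty margin (p is floored at 1e-300
  before the log).
* **SOR** — log of the pseudocount-stabilized symmetric odds ratio,
  scaled by the ref and alt min/max strand ratios.
* **Rank-sums** — Mann–Whitney U normal approximation with tie
  correction, signed alt-versus-ref, NaN when either group is empty and 0
  when the tie-corrected variance vanishes.

Multi-allelic records are decomposed into one call per ALT allele before
featurization, with allele-specific AD/AF selected; Varscan's percent-
string `FREQ` is parsed into a fraction at read time.

## Truth labeling and leakage control

Labels come from allele-exact matching against a truth call set after
both sides are normalized (shared-flank trimming + left-alignment of
indels), with zygosity ignored: a het call at a hom truth site with the
same allele is true. This replaces haplotype-replay comparison with its
reproducible core; complex MNP re-representations beyond
left-align+trim are out of scope and would label as false. Calls outside
a supplied confident-region BED are excluded by default (alternatively
labeled, via a flag), applied symmetrically to calls and truth.

Duplicate removal guards against leakage between training and test data:
an example is a duplicate iff its *entire* tuple — chromosome, position,
ref, alt, all 20 feature values (NaNs compared as equal), and label —
appears in the test set; duplicates are dropped from training only,
after the fold's training set is assembled. Cross-validation units are
individuals (LOIO: one fold per sample) or autosomes 1–22 (LOCO: 22
folds; non-autosomal calls are excluded with a logged count, since truth
sets do not consistently cover sex chromosomes).

## Evaluation framework

Positive class = true variant; majority class = true variants (real call
sets are true-dominated), so F1-major scores the true class and F1-minor
the false class. Undefined ratios (empty denominators) are reported as
NaN, never as 0. OFO = FN/TN is +∞ when FN>0, TN=0 and NaN when the
filter eliminated nothing; it deliberately isolates the composition of
the *eliminated* set, which NPV alone understates when eliminations are
rare.

Curve areas: AUC is the trapezoidal ROC area (equal to the pairwise
concordance probability — asserted against an exhaustive enumeration
oracle in the tests), AUPRC is interpolation-free average precision, and
AUPRG is the trapezoidal area in precision-gain/recall-gain space with
prevalence taken from the labels and points with recall below prevalence
clipped. Dichotomous filters (Frequency, Hard-Filter) have a single
operating point, so their areas use a three-point piecewise-linear
curve: ROC through (0,0), (FPR,TPR), (1,1); PR through (0,1),
(recall,precision), (1,prevalence); PRG through (0,1), (operating
point), (1,0) with the operating point clipped into the unit square. The
PR/PRG endpoint conventions are this package's choice of the standard
limits (precision → 1 at recall 0; precision → prevalence at recall 1).

Aggregation across folds/samples is reported **both** ways — arithmetic
mean of per-unit metrics (counts summed) and metrics recomputed from
pooled counts — because the two genuinely disagree for ratio metrics on
heterogeneous units; neither is privileged. Method comparisons use a
one-sided paired t-test per unit (null: no improvement), with stars at
p < 0.05 and p < 0.001; the zero-variance degenerate cases are defined
explicitly (identical vectors → p = 0.5, constant positive shift → 0)
since the t statistic is 0/0 there.

Stratifiers partition an evaluation set by VAF (high iff VAF ≥ 20%, the
boundary assigned high), by difficulty (easy iff *every* supplied
baseline verdict is correct), or by a coding-region BED.

## Synthetic data

`simulate_feature_dataset` draws class-conditional feature vectors:
Gaussian on unbounded features, logit-Gaussian on [0,1]-bounded ones,
with a single `class_separation` effect size shifting the class means of
the quality-like features (VAF, MBQ, MMQ, QUAL, QD, rank-sums upward for
true calls; FS, SOR downward). Rank-sum and MBQ features are masked
missing at a configurable rate (default 10%). Defaults emulate one
leave-one-out unit of a germline call set: 19,800 true + 198 false calls
(100:1) over 4 individuals and 22 autosomes with separation 2.0; the
generator reaches the extreme ratios real data shows (e.g. 2204:1) by
setting the class counts. Labels are exact by construction and
generation is deterministic per seed.

`simulate_alignment_fixture` writes a small random reference contig, a
sorted+indexed BAM of 100 bp uniformly tiled reads (match/single-indel
CIGARs only) with an exact planted alt-supporting count and strand
split, the matching single-sample VCF, a truth VCF containing the site
iff planted true, and a manifest. It exercises the real-format I/O and
featurization paths with known expected values.

What passing on this data shows — and does not: the synthetic features
are conditionally independent given the class, noise is homoscedastic,
and the read fixtures have uniform base quality and no alignment error.
Tests on them verify the contracts (schema, counts, thresholds,
determinism, metric identities, learnability and its absence), not
biological performance; results on real sequencing data depend on
caller- and cohort-specific feature distributions that this generator
does not model.

## Numerical and sizing choices

* Seeds flow from one integer through `numpy.random.default_rng` and the
  booster's `seed`; the featurize→train→score path is bit-stable per
  seed and fixture.
* Test problem sizes: the learning-sanity checks train on ~8–16k
  examples at 100:1 imbalance (seconds per fit on one CPU). The
  chance-level check (separation 0, AUC ≈ 0.5 within ±0.05) runs at 10:1
  with 900 minority examples: at 100:1 a 20% holdout holds only ~20
  minority calls and chance AUC fluctuates with sd ≈ 0.065, wider than
  the band being checked, so the instance is sized to make the check
  informative rather than the band widened.
* The Hard-Filter default rule set (SNV: QD<2, FS>60, MQ<40,
  MQRankSum<−12.5, ReadPosRankSum<−8; INDEL: QD<2, FS>200,
  ReadPosRankSum<−20) follows the widely published germline
  recommendations and is a stand-in for whatever thresholds a user's
  pipeline prescribes; rules are YAML-overridable and missing
  annotations pass a rule unless strict mode is set.
* VQSR-, GARFIELD-, VEF-style filters are not reimplemented; their
  verdicts enter the evaluation (and the difficulty stratifier) as
  externally produced FILTER-tagged VCFs.

## Known limitations

gVCF, structural variants, CRAM, phasing and multi-sample joint
labeling are out of scope. Genotype-aware (zygosity-matched) evaluation
is not provided. Scores are uncalibrated probabilities from the
logistic objective; no isotonic/Platt post-calibration is applied.
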