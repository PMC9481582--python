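# fvc — adaptive quality filtering for germline variant calls

Germline variant callers (GATK HaplotypeCaller, Mutect2, Varscan2,
DeepVariant) emit call sets in which true variants typically outnumber
artifacts by orders of magnitude, yet the artifacts that remain dominate
downstream error. `fvc` is a post-calling filter: it learns, from calls
labeled against a gold-standard truth set, a gradient-boosted classifier
over 20 per-variant features, annotates each call in a VCF with the
probability of being a true variant, and tags calls below a threshold
(default 0.5, strict `<`) as `Filtered`.

The package also implements an imbalance-aware evaluation framework built
around the **odds of false omission**

    OFO = FOR / (1 − FOR) = FN / TN,

the number of true variants eliminated per false variant removed (FN =
true variants filtered, TN = false variants filtered; FOR = FN/(TN+FN) is
the false omission rate and NPV = TN/(TN+FN) its complement). OFO ranges
over [0, +∞]: 0 means no true variant was lost, 1 means the eliminated
set is half true variants. Sixteen metrics are reported in total — AUC,
AUPRG, AUPRC (with a 3-point-curve rule for dichotomous filters), the
four confusion counts, F1-major/F1-minor, MCC, ACC, BACC, precision,
sensitivity, specificity, NPV and OFO — plus VAF / difficulty / region
stratifiers, leave-one-individual-out and leave-one-chromosome-out
cross-validation harnesses, and a one-sided paired t-test for method
comparisons.

Intended users: anyone post-processing single-sample germline VCFs who
has (or can simulate) truth labels, and anyone benchmarking variant
filters on imbalanced call sets.

## Library layout

| module | contents |
|---|---|
| `fvc.variant_io` | VCF/BAM/BED/FASTA reading, multi-allelic decomposition, pileup collection, score-annotated VCF writing |
| `fvc.features` | the 20-feature schema (4 sequence, 8 experiment, 8 analysis) and native annotation recomputation (FS, SOR, rank-sums) |
| `fvc.truthset` | allele normalization, zygosity-squashed truth labeling, duplicate/leakage removal, LOIO/LOCO folds |
| `fvc.classifier` | XGBoost training/scoring, 0.5-threshold classification, model bundles, feature importance |
| `fvc.baselines` | the Frequency filter (VAF < 20% or AD < 5 ⇒ filtered) and configurable Hard-Filter rules |
| `fvc.metrics` | the 16-metric report, OFO, 3-point curve areas, stratifiers, paired t-test |
| `fvc.simdata` | synthetic labeled feature tables and tiny FASTA/BAM/VCF fixtures |
| `fvc.cli` | `fvc {simulate,featurize,label,train,filter,evaluate}` |

## Worked example

Train on a simulated call set of 19,800 true and 198 false variants
(100:1 imbalance) and evaluate on a 20% holdout:

```python
import numpy as np
from fvc import SimConfig, simulate_feature_dataset, train, score_batch, classify, full_report

data = simulate_feature_dataset(SimConfig(n_true=19800, n_false=198, seed=7))
rng = np.random.default_rng(7)
idx = rng.permutation(len(data)); cut = int(0.8 * len(data))
tr, te = [data[i] for i in idx[:cut]], [data[i] for i in idx[cut:]]

model = train(tr, seed=7)
scores = score_batch(model, [e.features for e in te])
verdicts = [classify(float(s), model.threshold) for s in scores]
report = full_report([e.label for e in te], verdicts, scores)
```

This prints (rounded):

```
AUC 0.9772   MCC 0.5852   OFO 0.1875   NPV 0.8421
TP 3958  FP 23  FN 3  TN 16
F1_major 0.9967  F1_minor 0.5517  BACC 0.7047
```

Read it as: the filter eliminated 19 calls, 16 of them genuine artifacts,
losing 0.19 true variants per false variant removed (OFO), while keeping
99.9% of true variants (sensitivity). The gap between ACC (0.99) and
BACC (0.70), and between F1-major and F1-minor, is why the imbalance-
aware metrics are reported at all.

The same workflow runs from the shell on real files:

```sh
fvc featurize --vcf calls.vcf --bam sample.bam --ref ref.fa --out features.tsv
fvc label     --features-table features.tsv --vcf calls.vcf \
              --truth-vcf giab.vcf --confident-bed giab.bed --out labeled.tsv
fvc train     --labeled-table labeled.tsv --seed 1 --out model.json
fvc filter    --vcf calls.vcf --bam sample.bam --ref ref.fa \
              --model model.json --out filtered.vcf
fvc evaluate  --labeled-table labeled.tsv --cv loco --out report.json
```

`filtered.vcf` carries the probability in `INFO/FVC_SCORE` and
`Filtered`/`PASS` in FILTER; `report.json` holds one 16-metric report per
fold plus mean-over-folds and pooled-counts aggregations.

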