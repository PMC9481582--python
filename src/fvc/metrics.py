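"""Imbalance-aware evaluation of variant filters.

Sixteen metrics summarize a filter's behaviour on a labeled call set:
three threshold-free curve areas (AUC, AUPRG, AUPRC), the four confusion
counts, eight threshold metrics (F1-major, F1-minor, MCC, ACC, BACC,
precision, sensitivity, specificity) plus NPV, and the odds of false
omission

    OFO = FOR / (1 - FOR) = FN / TN,

the number of true variants lost per false variant removed.  OFO ranges
over [0, +inf]: 0 means no true variant was eliminated, 1 means the
eliminated set is half true variants, +inf means true variants were
eliminated but no false one was.

Conventions fixed throughout: the positive class is the TRUE variant;
true call sets dominate, so F1-major scores the true class and F1-minor
the false class; a call whose score equals the threshold is retained
(strict ``<``).

Dichotomous filters have a single operating point, so their curve areas
are computed from a three-point piecewise-linear curve through (0, y1),
(x2, y2), (1, y3) — e.g. for ROC, (0,0), (FPR, TPR), (1,1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sstats
from sklearn.metrics import average_precision_score, roc_auc_score

from fvc.classifier import FILTERED, RETAINED

MISSING = math.nan

#: names of the sixteen metrics reported by :func:`full_report`
METRIC_NAMES = [
    "AUC", "AUPRG", "AUPRC",
    "TP", "FP", "FN", "TN",
    "F1_major", "F1_minor", "MCC", "ACC", "BACC",
    "Precision", "Sensitivity", "Specificity",
    "NPV", "OFO",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP: true variants retained; FP: false retained; FN: true
    eliminated; TN: false eliminated."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def _as_bool_labels(labels) -> np.ndarray:
    return np.asarray([bool(x) for x in labels], dtype=bool)


def _as_retained(verdicts) -> np.ndarray:
    out = []
    for v in verdicts:
        if v in (RETAINED, True, "keep", "PASS"):
            out.append(True)
        elif v in (FILTERED, False, "drop", "Filtered"):
            out.append(False)
        else:
            raise ValueError(f"unrecognized verdict {v!r}")
    return np.asarray(out, dtype=bool)


def confusion(labels, verdicts) -> ConfusionCounts:
    """Count the confusion cells; ``labels`` are truth (True = true
    variant), ``verdicts`` are RETAINED/FILTERED decisions."""
    y = _as_bool_labels(labels)
    kept = _as_retained(verdicts)
    if len(y) != len(kept):
        raise ValueError(f"length mismatch: {len(y)} labels vs {len(kept)} verdicts")
    return ConfusionCounts(
        TP=int(np.sum(y & kept)),
        FP=int(np.sum(~y & kept)),
        FN=int(np.sum(y & ~kept)),
        TN=int(np.sum(~y & ~kept)),
    )


def npv(c: ConfusionCounts) -> float:
    """Negative predictive value TN / (TN + FN); MISSING when nothing
    was eliminated."""
    denom = c.TN + c.FN
    return c.TN / denom if denom > 0 else MISSING


def ofo(c: ConfusionCounts) -> float:
    """Odds of false omission FN / TN.

    +inf when true variants were eliminated but no false one; MISSING
    when the filter eliminated nothing at all.
    """
    if c.TN > 0:
        return c.FN / c.TN
    if c.FN > 0:
        return math.inf
    return MISSING


def _safe_div(num: float, denom: float) -> float:
    return num / denom if denom > 0 else MISSING


def threshold_metrics(c: ConfusionCounts) -> dict[str, float]:
    """The threshold-dependent metrics; undefined cells are MISSING,
    never silently zero."""
    tp, fp, fn, tn = c.TP, c.FP, c.FN, c.TN
    precision = _safe_div(tp, tp + fp)
    sensitivity = _safe_div(tp, tp + fn)  # TPR, recall of true variants
    specificity = _safe_div(tn, tn + fp)  # TNR
    f1_major = _safe_div(2 * tp, 2 * tp + fp + fn)
    f1_minor = _safe_div(2 * tn, 2 * tn + fn + fp)
    acc = _safe_div(tp + tn, c.total)
    bacc = (sensitivity + specificity) / 2 if not (
        math.isnan(sensitivity) or math.isnan(specificity)) else MISSING
    mcc_denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / mcc_denom if mcc_denom > 0 else MISSING
    return {
        "TP": tp, "FP": fp, "FN": fn, "TN": tn,
        "F1_major": f1_major, "F1_minor": f1_minor,
        "MCC": mcc, "ACC": acc, "BACC": bacc,
        "Precision": precision, "Sensitivity": sensitivity,
        "Specificity": specificity,
        "NPV": npv(c), "OFO": ofo(c),
    }


def _prg_points(labels: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Precision-gain/recall-gain curve points sorted by recall-gain.

    Gains are 1 - pi/rec * (1-rec)/(1-pi) style transforms of precision
    and recall with prevalence pi; points with recall < pi (negative
    recall-gain) lie outside the unit square and are dropped.
    """
    pi = labels.mean()
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    s = scores[order]
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    # one operating point per distinct threshold
    distinct = np.r_[np.where(np.diff(s) != 0)[0], len(s) - 1]
    tps, fps = tps[distinct], fps[distinct]
    rec = tps / tps[-1]
    prec = tps / (tps + fps)
    with np.errstate(divide="ignore", invalid="ignore"):
        rg = 1.0 - (pi / (1.0 - pi)) * ((1.0 - rec) / rec)
        pg = 1.0 - (pi / (1.0 - pi)) * ((1.0 - prec) / prec)
    keep = rec >= pi
    rg, pg = rg[keep], np.clip(pg[keep], 0.0, 1.0)
    rg = np.clip(rg, 0.0, 1.0)
    return rg, pg


def auprg(labels, scores) -> float:
    """Area under the precision-recall-gain curve (trapezoidal, in
    recall-gain space with prevalence taken from the labels)."""
    y = _as_bool_labels(labels)
    s = np.asarray(scores, dtype=float)
    if y.all() or (~y).all():
        return MISSING
    rg, pg = _prg_points(y, s)
    if len(rg) == 0:
        return 0.0
    # extend to the full [0, 1] recall-gain range
    rg = np.r_[0.0, rg]
    pg = np.r_[pg[0], pg]
    if rg[-1] < 1.0:
        rg = np.r_[rg, 1.0]
        pg = np.r_[pg, pg[-1]]
    return float(np.trapezoid(pg, rg))


def curve_metrics(labels, scores) -> dict[str, float]:
    """Threshold-free areas {AUC, AUPRC, AUPRG} from continuous scores.

    AUC is the trapezoidal ROC area (equivalently the pairwise
    concordance probability); AUPRC is interpolation-free average
    precision; both are MISSING for single-class inputs.
    """
    y = _as_bool_labels(labels)
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ValueError("labels and scores must align")
    if y.all() or (~y).all():
        return {"AUC": MISSING, "AUPRC": MISSING, "AUPRG": MISSING}
    return {
        "AUC": float(roc_auc_score(y, s)),
        "AUPRC": float(average_precision_score(y, s)),
        "AUPRG": auprg(y, s),
    }


def three_point_curve_metrics(c: ConfusionCounts, which: str = "AUC") -> float:
    """Curve area for a dichotomous filter from its single operating
    point, via the three-point piecewise-linear curve (0, y1), (x2, y2),
    (1, y3).

    ROC: (0,0) -> (FPR, TPR) -> (1,1).  PR: (0,1) -> (recall, precision)
    -> (1, prevalence).  PRG: (0,1) -> (recall-gain, precision-gain) ->
    (1,0), with the operating point clipped into the unit square.
    """
    pos = c.TP + c.FN
    neg = c.FP + c.TN
    if which == "AUC":
        if pos == 0 or neg == 0:
            return MISSING
        x2, y2 = c.FP / neg, c.TP / pos
        points = [(0.0, 0.0), (x2, y2), (1.0, 1.0)]
    elif which == "AUPRC":
        if pos == 0:
            return MISSING
        rec = c.TP / pos
        prec = _safe_div(c.TP, c.TP + c.FP)
        if math.isnan(prec):
            prec = 1.0  # nothing retained: vacuous precision at recall 0
        pi = pos / c.total
        points = [(0.0, 1.0), (rec, prec), (1.0, pi)]
    elif which == "AUPRG":
        if pos == 0 or neg == 0:
            return MISSING
        pi = pos / c.total
        rec = c.TP / pos
        prec = _safe_div(c.TP, c.TP + c.FP)
        if math.isnan(prec):
            prec = 1.0
        factor = pi / (1.0 - pi)
        rg = 1.0 - factor * (1.0 - rec) / rec if rec > 0 else 0.0
        pg = 1.0 - factor * (1.0 - prec) / prec if prec > 0 else 0.0
        points = [(0.0, 1.0), (min(max(rg, 0.0), 1.0), min(max(pg, 0.0), 1.0)), (1.0, 0.0)]
    else:
        raise ValueError("which must be AUC, AUPRC or AUPRG")
    points.sort(key=lambda p: p[0])
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    return float(np.trapezoid(ys, xs))


def full_report(labels, verdicts, scores=None) -> dict[str, float]:
    """All sixteen metrics for one filter on one labeled call set.

    With continuous ``scores`` the curve areas are threshold-free; for a
    dichotomous filter (no scores) they fall back to the 3-point rule.
    """
    c = confusion(labels, verdicts)
    report = dict.fromkeys(METRIC_NAMES, MISSING)
    report.update(threshold_metrics(c))
    if scores is not None:
        report.update(curve_metrics(labels, scores))
    else:
        for which in ("AUC", "AUPRC", "AUPRG"):
            report[which] = three_point_curve_metrics(c, which)
    return {k: report[k] for k in METRIC_NAMES}


def aggregate_reports(reports: list[dict[str, float]]) -> dict[str, dict[str, float]]:
    """Combine per-unit (per-sample / per-fold) reports two ways.

    ``mean``: arithmetic mean of each metric over units (counts summed);
    ``pooled``: metrics recomputed from the summed confusion counts.
    The two disagree for ratio metrics on heterogeneous units, so both
    are reported.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    mean: dict[str, float] = {}
    for name in METRIC_NAMES:
        vals = [r[name] for r in reports if not math.isnan(r.get(name, MISSING))]
        if name in ("TP", "FP", "FN", "TN"):
            mean[name] = float(np.sum([r[name] for r in reports]))
        else:
            mean[name] = float(np.mean(vals)) if vals else MISSING
    pooled_counts = ConfusionCounts(
        TP=int(sum(r["TP"] for r in reports)),
        FP=int(sum(r["FP"] for r in reports)),
        FN=int(sum(r["FN"] for r in reports)),
        TN=int(sum(r["TN"] for r in reports)),
    )
    pooled = dict.fromkeys(METRIC_NAMES, MISSING)
    pooled.update(threshold_metrics(pooled_counts))
    return {"mean": mean, "pooled": pooled}


def stratify(examples, mode: str, aux=None) -> dict[str, list]:
    """Partition examples into evaluation subgroups.

    mode="vaf": high (VAF >= 0.20) vs low; examples are LabeledExample
    or anything with ``.features.values["VAF"]``.
    mode="difficulty": easy iff every supplied baseline verdict is
    correct; ``aux`` is {"labels": [...], "baseline_verdicts":
    [[...], ...]} with one verdict list per baseline, aligned to
    examples.
    mode="region": coding iff inside ``aux`` intervals ({chrom: [(start1,
    end1), ...]}); examples need ``.key`` loci.
    """
    if mode == "vaf":
        high, low = [], []
        for ex in examples:
            vaf = ex.features.values["VAF"]
            if math.isnan(vaf):
                raise ValueError(f"example {ex.key} has no VAF")
            (high if vaf >= 0.20 else low).append(ex)
        return {"high_vaf": high, "low_vaf": low}

    if mode == "difficulty":
        if not aux or "labels" not in aux or not aux.get("baseline_verdicts"):
            raise ValueError("difficulty mode needs labels and >=1 baseline verdict lists")
        labels = _as_bool_labels(aux["labels"])
        verdict_sets = [_as_retained(v) for v in aux["baseline_verdicts"]]
        for vs in verdict_sets:
            if len(vs) != len(examples):
                raise ValueError("baseline verdicts must align with examples")
        easy, hard = [], []
        for i, ex in enumerate(examples):
            correct = all(vs[i] == labels[i] for vs in verdict_sets)
            (easy if correct else hard).append(ex)
        return {"easy": easy, "hard": hard}

    if mode == "region":
        if aux is None:
            raise ValueError("region mode needs coding intervals")
        from fvc.truthset import _region_trees
        trees = _region_trees(aux)
        coding, noncoding = [], []
        for ex in examples:
            chrom, pos = ex.key[0], ex.key[1]
            tree = trees.get(chrom)
            inside = bool(tree is not None and tree.overlaps_point(pos))
            (coding if inside else noncoding).append(ex)
        return {"coding": coding, "noncoding": noncoding}

    raise ValueError("mode must be vaf, difficulty or region")


def paired_onesided_ttest(metric_a, metric_b) -> float:
    """One-sided paired t-test p-value for mean(a - b) > 0.

    The null is that method A performs no better than method B on the
    paired per-unit metric values.  Degenerate zero-variance cases:
    identical vectors give p = 0.5; a constant positive shift gives 0.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors of equal length required")
    if len(a) < 2:
        raise ValueError("need at least 2 paired observations")
    d = a - b
    if np.all(d == d[0]):  # zero variance of differences
        if d[0] == 0:
            return 0.5
        return 0.0 if d[0] > 0 else 1.0
    res = _sstats.ttest_rel(a, b, alternative="greater")
    return float(res.pvalue)


def significance_stars(p: float) -> str:
    """Annotation convention: * for p < 0.05, ** for p < 0.001."""
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""
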