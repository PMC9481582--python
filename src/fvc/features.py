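"""Per-variant feature construction.

Each call is described by 20 numeric features in three categories:

* sequence (4) — properties of the reference context around the locus
  (variant type, GC content, homopolymer run, tandem-repeat copies of
  the indel unit);
* experiment (8) — read-level evidence from the pileup (depth, alt
  support, VAF, base/mapping quality summaries, strand balance, read
  position);
* analysis (8) — caller annotations (QUAL, QD, GQ, FS, SOR and the
  three rank-sum tests).

Annotation-style features are recomputed natively from the pileup when a
caller did not emit them; values present in INFO/FORMAT take precedence
so that caller provenance is honored.  Missing values are represented as
NaN and passed through to the booster natively — never zero-filled.

The schema is data, not code: ``FEATURE_SCHEMA`` is an ordered list of
(name, category) pairs and serialized tables / model bundles carry it
verbatim, so substituting a different feature set is a schema change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from fvc.variant_io import VariantCall, PileupContext

MISSING = math.nan

#: canonical feature schema: (name, category), order is contractual
FEATURE_SCHEMA: list[tuple[str, str]] = [
    ("VARTYPE", "sequence"),
    ("GC_CONTENT", "sequence"),
    ("HOMOPOLYMER_RUN", "sequence"),
    ("REPEAT_UNITS", "sequence"),
    ("DP", "experiment"),
    ("AD_ALT", "experiment"),
    ("VAF", "experiment"),
    ("MBQ_ALT", "experiment"),
    ("MMQ", "experiment"),
    ("MQ0_FRAC", "experiment"),
    ("STRAND_BALANCE", "experiment"),
    ("MEDIAN_READPOS_ALT", "experiment"),
    ("QUAL", "analysis"),
    ("QD", "analysis"),
    ("GQ", "analysis"),
    ("FS", "analysis"),
    ("SOR", "analysis"),
    ("MQ_RANKSUM", "analysis"),
    ("READPOS_RANKSUM", "analysis"),
    ("BASEQ_RANKSUM", "analysis"),
]

FEATURE_NAMES: list[str] = [name for name, _ in FEATURE_SCHEMA]
FEATURE_CATEGORIES: dict[str, str] = dict(FEATURE_SCHEMA)

# INFO keys under which callers emit the analysis-style annotations
_INFO_ALIASES = {
    "DP": ("DP",),
    "QD": ("QD",),
    "FS": ("FS",),
    "SOR": ("SOR",),
    "MQ_RANKSUM": ("MQRankSum",),
    "READPOS_RANKSUM": ("ReadPosRankSum",),
    "BASEQ_RANKSUM": ("BaseQRankSum",),
    "MMQ": ("MQ", "MMQ"),
}

DEFAULT_FLANK = 50


@dataclass
class FeatureVector:
    """The 20 named features for one call, NaN marking missing values."""

    key: tuple  # (chrom, pos, ref, alt, sample_id)
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        extra = set(self.values) - set(FEATURE_NAMES)
        missing = set(FEATURE_NAMES) - set(self.values)
        if extra or missing:
            raise ValueError(f"schema mismatch: extra={sorted(extra)} missing={sorted(missing)}")
        vaf = self.values.get("VAF", MISSING)
        if not math.isnan(vaf) and not (0.0 <= vaf <= 1.0):
            raise ValueError(f"VAF {vaf} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES], dtype=float)


def gc_content(window: str) -> float:
    """GC fraction of a sequence window; N bases are excluded from the
    denominator and an all-N window is MISSING."""
    if not window:
        raise ValueError("empty window")
    window = window.upper()
    acgt = sum(window.count(b) for b in "ACGT")
    if acgt == 0:
        return MISSING
    return (window.count("G") + window.count("C")) / acgt


def homopolymer_run(window: str, offset: int) -> int:
    """Length of the homopolymer run through position ``offset`` (0-based
    index into ``window``)."""
    if not (0 <= offset < len(window)):
        raise IndexError("offset outside window")
    base = window[offset].upper()
    w = window.upper()
    left = offset
    while left > 0 and w[left - 1] == base:
        left -= 1
    right = offset
    while right + 1 < len(w) and w[right + 1] == base:
        right += 1
    return right - left + 1


def repeat_units(call: VariantCall, window: str, offset: int) -> int:
    """Tandem copies of the indel unit in the reference downstream of the
    anchor base; 0 for SNVs and when the unit is not repeated there."""
    if call.vtype == "SNV":
        return 0
    if len(call.alt) > len(call.ref):
        unit = call.alt[len(call.ref):]
    else:
        unit = call.ref[len(call.alt):]
    if not unit:
        return 0
    w = window.upper()
    unit = unit.upper()
    start = offset + len(call.ref)  # first base after the REF span
    count = 0
    i = start
    while w[i:i + len(unit)] == unit:
        count += 1
        i += len(unit)
    return count


def strand_bias_fs(pileup: PileupContext) -> float:
    """Phred-scaled two-sided Fisher exact p for ref/alt × strand
    association (the FS-style annotation); 0 for degenerate tables."""
    rf = sum(1 for r in pileup.ref_reads if r.forward_strand)
    rr = sum(1 for r in pileup.ref_reads if not r.forward_strand)
    af = sum(1 for r in pileup.alt_reads if r.forward_strand)
    ar = sum(1 for r in pileup.alt_reads if not r.forward_strand)
    if min(rf + rr, af + ar) == 0 or min(rf + af, rr + ar) == 0:
        return 0.0
    _, p = stats.fisher_exact([[rf, rr], [af, ar]], alternative="two-sided")
    p = max(float(p), 1e-300)
    return max(0.0, -10.0 * math.log10(p))


def strand_odds_ratio(pileup: PileupContext) -> float:
    """Symmetric strand odds ratio (SOR-style annotation), the log of the
    pseudocount-stabilized symmetric odds ratio scaled by the ref/alt
    min-to-max strand ratios."""
    rf = sum(1 for r in pileup.ref_reads if r.forward_strand) + 1
    rr = sum(1 for r in pileup.ref_reads if not r.forward_strand) + 1
    af = sum(1 for r in pileup.alt_reads if r.forward_strand) + 1
    ar = sum(1 for r in pileup.alt_reads if not r.forward_strand) + 1
    ratio = (rf * ar) / (rr * af) + (rr * af) / (rf * ar)
    ref_ratio = min(rf, rr) / max(rf, rr)
    alt_ratio = min(af, ar) / max(af, ar)
    return math.log(ratio) + math.log(ref_ratio) - math.log(alt_ratio)


def rank_sum_z(values_ref: list[float], values_alt: list[float]) -> float:
    """Mann–Whitney rank-sum z-score (normal approximation with tie
    correction), signed alt-versus-ref; MISSING when either side is empty.
    """
    ref = [v for v in values_ref if not math.isnan(v)]
    alt = [v for v in values_alt if not math.isnan(v)]
    n1, n2 = len(alt), len(ref)
    if n1 == 0 or n2 == 0:
        return MISSING
    pooled = np.asarray(alt + ref, dtype=float)
    ranks = stats.rankdata(pooled)
    r_alt = ranks[:n1].sum()
    u_alt = r_alt - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0
    return float((u_alt - mu) / math.sqrt(var))


def _median(values: list[float]) -> float:
    vals = [v for v in values if not math.isnan(v)]
    return float(np.median(vals)) if vals else MISSING


def _from_info(call: VariantCall, feature: str) -> float | None:
    for key in _INFO_ALIASES.get(feature, ()):
        if key in call.info and call.info[key] is not None:
            try:
                return float(call.info[key])
            except (TypeError, ValueError):
                continue
    return None


def featurize(call: VariantCall, pileup: PileupContext,
              refseq: str, window_start: int = 1) -> FeatureVector:
    """Build the 20-feature vector for one call.

    ``refseq`` is the reference sequence window covering the locus and
    ``window_start`` its 1-based start coordinate; the window must cover
    ``call.pos`` (± the configured flank for sequence features).
    """
    offset = call.pos - window_start
    if not (0 <= offset < len(refseq)):
        raise IndexError(
            f"reference window [{window_start}, {window_start + len(refseq)}) "
            f"does not cover position {call.pos}")

    v: dict[str, float] = {}
    v["VARTYPE"] = 0.0 if call.vtype == "SNV" else 1.0
    lo = max(0, offset - DEFAULT_FLANK)
    hi = min(len(refseq), offset + DEFAULT_FLANK + 1)
    v["GC_CONTENT"] = gc_content(refseq[lo:hi])
    v["HOMOPOLYMER_RUN"] = float(homopolymer_run(refseq, offset))
    v["REPEAT_UNITS"] = float(repeat_units(call, refseq, offset))

    alt_reads = pileup.alt_reads
    ref_reads = pileup.ref_reads

    dp_info = _from_info(call, "DP")
    dp_fmt = call.fmt.get("DP")
    dp = dp_info if dp_info is not None else (float(dp_fmt) if dp_fmt is not None else float(pileup.depth))
    v["DP"] = dp

    ad = call.fmt.get("AD_ALT")
    v["AD_ALT"] = float(ad) if ad is not None else float(len(alt_reads))

    af = call.fmt.get("AF")
    if af is not None:
        v["VAF"] = float(af)
    elif dp and dp > 0:
        v["VAF"] = min(1.0, v["AD_ALT"] / dp)
    elif pileup.depth == 0:
        v["VAF"] = 0.0
    else:
        v["VAF"] = MISSING

    v["MBQ_ALT"] = _median([r.base_quality for r in alt_reads])
    mmq = _from_info(call, "MMQ")
    v["MMQ"] = mmq if mmq is not None else _median([float(r.mapping_quality) for r in pileup.reads])
    v["MQ0_FRAC"] = (sum(1 for r in pileup.reads if r.mapping_quality == 0) / pileup.depth
                     if pileup.depth else MISSING)
    v["STRAND_BALANCE"] = (sum(1 for r in alt_reads if r.forward_strand) / len(alt_reads)
                           if alt_reads else MISSING)
    v["MEDIAN_READPOS_ALT"] = _median([r.dist_from_end for r in alt_reads])

    v["QUAL"] = float(call.qual) if call.qual is not None else MISSING
    qd = _from_info(call, "QD")
    if qd is not None:
        v["QD"] = qd
    elif not math.isnan(v["QUAL"]) and dp and dp > 0:
        v["QD"] = v["QUAL"] / dp
    else:
        v["QD"] = MISSING
    gq = call.fmt.get("GQ")
    v["GQ"] = float(gq) if gq is not None else MISSING

    fs = _from_info(call, "FS")
    v["FS"] = fs if fs is not None else strand_bias_fs(pileup)
    sor = _from_info(call, "SOR")
    v["SOR"] = sor if sor is not None else strand_odds_ratio(pileup)

    rs = _from_info(call, "MQ_RANKSUM")
    v["MQ_RANKSUM"] = rs if rs is not None else rank_sum_z(
        [float(r.mapping_quality) for r in ref_reads],
        [float(r.mapping_quality) for r in alt_reads])
    rs = _from_info(call, "READPOS_RANKSUM")
    v["READPOS_RANKSUM"] = rs if rs is not None else rank_sum_z(
        [r.dist_from_end for r in ref_reads], [r.dist_from_end for r in alt_reads])
    rs = _from_info(call, "BASEQ_RANKSUM")
    v["BASEQ_RANKSUM"] = rs if rs is not None else rank_sum_z(
        [r.base_quality for r in ref_reads], [r.base_quality for r in alt_reads])

    return FeatureVector(key=call.key, values=v)


def vectors_to_frame(vectors: list[FeatureVector]):
    """Stack feature vectors into a pandas DataFrame with key columns first."""
    import pandas as pd

    rows = []
    for fv in vectors:
        chrom, pos, ref, alt, sid = fv.key
        row = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "sample_id": sid}
        row.update({n: fv.values[n] for n in FEATURE_NAMES})
        rows.append(row)
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "sample_id"] + FEATURE_NAMES)
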