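"""Rule-based comparator filters.

Two fully specified unsupervised baselines used for benchmarking and for
the easy/hard-to-detect stratifier:

* Frequency — a call is a false variant when its VAF is below 20% or its
  alt allelic depth is below 5 (both strict);
* Hard-Filter — user-selected threshold rules on caller annotations.
  The shipped defaults follow the widely used germline hard-filter
  recommendations (SNV: QD<2, FS>60, MQ<40, MQRankSum<-12.5,
  ReadPosRankSum<-8; INDEL: QD<2, FS>200, ReadPosRankSum<-20) and are
  fully overridable via YAML.

A call missing a rule's annotation passes that rule by default
(the permissive convention); ``strict_missing=True`` filters it instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import yaml

from fvc.classifier import FILTERED, RETAINED
from fvc.features import FeatureVector

VAF_THRESHOLD = 0.20
AD_THRESHOLD = 5

_COMPARATORS = {
    "<": lambda v, t: v < t,
    ">": lambda v, t: v > t,
    "<=": lambda v, t: v <= t,
    ">=": lambda v, t: v >= t,
}


def frequency_filter(vaf: float, ad_alt: float) -> str:
    """FILTERED iff VAF < 0.20 or alt allelic depth < 5 (both strict)."""
    if not (0.0 <= vaf <= 1.0):
        raise ValueError(f"vaf {vaf} outside [0, 1]")
    if ad_alt < 0:
        raise ValueError("ad_alt must be >= 0")
    return FILTERED if (vaf < VAF_THRESHOLD or ad_alt < AD_THRESHOLD) else RETAINED


@dataclass(frozen=True)
class HardFilterRule:
    """One threshold condition: trigger ⇒ filter the call."""

    annotation: str
    comparator: str  # one of < > <= >=
    threshold: float
    vtype: str = "both"  # SNV | INDEL | both

    def __post_init__(self):
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"comparator must be one of {sorted(_COMPARATORS)}")
        if not math.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.vtype not in ("SNV", "INDEL", "both"):
            raise ValueError("vtype must be SNV, INDEL or both")

    def applies_to(self, vtype: str) -> bool:
        return self.vtype == "both" or self.vtype == vtype

    def triggers(self, value: float) -> bool:
        return not math.isnan(value) and _COMPARATORS[self.comparator](value, self.threshold)


DEFAULT_HARD_FILTER_RULES: list[HardFilterRule] = [
    HardFilterRule("QD", "<", 2.0, "SNV"),
    HardFilterRule("FS", ">", 60.0, "SNV"),
    HardFilterRule("MMQ", "<", 40.0, "SNV"),
    HardFilterRule("MQ_RANKSUM", "<", -12.5, "SNV"),
    HardFilterRule("READPOS_RANKSUM", "<", -8.0, "SNV"),
    HardFilterRule("QD", "<", 2.0, "INDEL"),
    HardFilterRule("FS", ">", 200.0, "INDEL"),
    HardFilterRule("READPOS_RANKSUM", "<", -20.0, "INDEL"),
]


def _annotation_value(fv: FeatureVector, call_info: dict | None, name: str) -> float:
    if name in fv.values:
        return fv.values[name]
    if call_info and name in call_info and call_info[name] is not None:
        try:
            return float(call_info[name])
        except (TypeError, ValueError):
            return math.nan
    return math.nan


def hard_filter(fv: FeatureVector, vtype: str,
                rules: list[HardFilterRule] | None = None,
                call_info: dict | None = None,
                strict_missing: bool = False) -> str:
    """FILTERED iff any applicable rule's condition triggers.

    Annotations are looked up in the feature vector first, then in the
    raw INFO map.  Missing annotations pass the rule unless
    ``strict_missing`` is set.
    """
    if rules is None:
        rules = DEFAULT_HARD_FILTER_RULES
    if not rules:
        raise ValueError("rules must be non-empty")
    for rule in rules:
        if not rule.applies_to(vtype):
            continue
        value = _annotation_value(fv, call_info, rule.annotation)
        if math.isnan(value):
            if strict_missing:
                return FILTERED
            continue
        if rule.triggers(value):
            return FILTERED
    return RETAINED


def check_rules_usable(vectors: list[FeatureVector],
                       rules: list[HardFilterRule]) -> None:
    """Warn when a rule's annotation is absent from every call."""
    for rule in rules:
        if all(math.isnan(_annotation_value(fv, None, rule.annotation)) for fv in vectors):
            warnings.warn(
                f"hard-filter rule on {rule.annotation!r} matches no call: "
                "annotation missing everywhere", UserWarning, stacklevel=2)


def load_rules(path) -> list[HardFilterRule]:
    """Load a rule set from YAML: a list of {annotation, comparator,
    threshold, vtype} mappings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [HardFilterRule(r["annotation"], r["comparator"],
                           float(r["threshold"]), r.get("vtype", "both"))
            for r in raw]
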