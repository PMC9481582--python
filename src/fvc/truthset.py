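"""Truth labeling, leakage-safe training-set assembly and CV folds.

Calls are compared with a gold-standard call set by allele-exact matching
after normalization (left-alignment + trimming of shared flanking
bases), with zygosity ignored: a het call at a hom truth site with the
same allele is a true variant.  Class imbalance is preserved end to end —
nothing here resamples or reweights.

The leakage rule: a training example whose full tuple (chrom, pos, ref,
alt, all feature values, label) also occurs in the test set is dropped
from training; the test set is never touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from intervaltree import IntervalTree

from fvc.features import FEATURE_NAMES, FeatureVector
from fvc.variant_io import VariantCall

TRUE_VARIANT = True
FALSE_VARIANT = False

AUTOSOMES = [str(i) for i in range(1, 23)]


class ReferenceMismatchError(ValueError):
    """The call's REF allele disagrees with the reference sequence."""


@dataclass(frozen=True)
class LabeledExample:
    """A feature vector with its truth label."""

    key: tuple  # (chrom, pos, ref, alt, sample_id)
    features: FeatureVector
    label: bool  # True == true variant

    @property
    def chrom(self) -> str:
        return self.key[0]

    @property
    def sample_id(self) -> str:
        return self.key[4]

    def full_tuple(self) -> tuple:
        """Duplicate identity: locus, alleles, every feature value, label.

        NaNs are canonicalized so that two vectors missing the same
        feature compare equal.
        """
        chrom, pos, ref, alt, _ = self.key
        vals = tuple(
            ("NA" if math.isnan(self.features.values[n]) else self.features.values[n])
            for n in FEATURE_NAMES
        )
        return (chrom, pos, ref, alt, vals, self.label)


@dataclass
class CvFold:
    fold_id: str
    train: list[LabeledExample]
    test: list[LabeledExample]
    held_out_unit: str = ""


class _SeqAccessor:
    """Uniform fetch(chrom, start0, end0) over pysam.FastaFile or a dict
    of contig sequences (handy in tests)."""

    def __init__(self, reference):
        self._ref = reference

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        if isinstance(self._ref, dict):
            return self._ref[chrom][start0:end0].upper()
        return self._ref.fetch(chrom, start0, end0).upper()


def normalize_variant(call: VariantCall, reference) -> VariantCall:
    """Left-align and trim a variant to its canonical representation.

    ``reference`` is a pysam.FastaFile or a {contig: sequence} dict.
    SNVs pass through unchanged apart from the reference-agreement check.
    """
    acc = _SeqAccessor(reference)
    pos, ref, alt = call.pos, call.ref.upper(), call.alt.upper()
    seq_ref = acc.fetch(call.chrom, pos - 1, pos - 1 + len(ref))
    if seq_ref != ref:
        raise ReferenceMismatchError(
            f"{call.chrom}:{pos} REF {ref} != reference {seq_ref}")

    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        elif ref[-1] == alt[-1] and (len(ref) == 1 or len(alt) == 1) and pos > 1:
            prev = acc.fetch(call.chrom, pos - 2, pos - 1)
            if not prev:
                break
            pos -= 1
            ref, alt = prev + ref[:-1], prev + alt[:-1]
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1

    if pos == call.pos and ref == call.ref and alt == call.alt:
        return call
    vtype = "SNV" if len(ref) == 1 and len(alt) == 1 else "INDEL"
    return replace(call, pos=pos, ref=ref, alt=alt, vtype=vtype)


def _region_trees(regions: dict[str, list[tuple[int, int]]]) -> dict[str, IntervalTree]:
    trees = {}
    for chrom, ivs in regions.items():
        t = IntervalTree()
        for start1, end1 in ivs:  # 1-based inclusive
            t.addi(start1, end1 + 1)
        trees[chrom] = t
    return trees


def label_calls(calls: list[VariantCall], truth: list[VariantCall],
                confident_regions: dict[str, list[tuple[int, int]]] | None = None,
                reference=None,
                outside_confident: str = "exclude") -> list[tuple[VariantCall, bool]]:
    """Label each call true/false by allele-exact match against the truth set.

    Genotype/zygosity is ignored (squash-ploidy semantics).  When
    ``reference`` is given both call and truth alleles are normalized
    first.  Calls outside ``confident_regions`` (1-based inclusive
    intervals per contig) are excluded by default, or labeled anyway with
    ``outside_confident="label"``.
    """
    if outside_confident not in ("exclude", "label"):
        raise ValueError("outside_confident must be 'exclude' or 'label'")

    def norm(c: VariantCall) -> VariantCall:
        return normalize_variant(c, reference) if reference is not None else c

    truth_keys = {(t.chrom, t.pos, t.ref.upper(), t.alt.upper()) for t in map(norm, truth)}
    trees = _region_trees(confident_regions) if confident_regions is not None else None

    out: list[tuple[VariantCall, bool]] = []
    for call in calls:
        ncall = norm(call)
        if trees is not None:
            tree = trees.get(ncall.chrom)
            inside = bool(tree is not None and tree.overlaps_point(ncall.pos))
            if not inside and outside_confident == "exclude":
                continue
        label = (ncall.chrom, ncall.pos, ncall.ref.upper(), ncall.alt.upper()) in truth_keys
        out.append((call, label))
    return out


def deduplicate(train: list[LabeledExample], test: list[LabeledExample]) -> list[LabeledExample]:
    """Drop training examples whose full tuple also appears in the test set."""
    for ex in list(train) + list(test):
        if set(ex.features.values) != set(FEATURE_NAMES):
            raise ValueError("feature schema mismatch between examples")
    test_tuples = {ex.full_tuple() for ex in test}
    return [ex for ex in train if ex.full_tuple() not in test_tuples]


def split_loio(examples: list[LabeledExample]) -> list[CvFold]:
    """Leave-one-individual-out folds: one fold per sample, that sample's
    examples as test, everything else (deduplicated) as train."""
    samples: list[str] = []
    for ex in examples:
        if ex.sample_id not in samples:
            samples.append(ex.sample_id)
    if len(samples) < 2:
        raise ValueError("leave-one-individual-out needs at least 2 samples")
    folds = []
    for sid in samples:
        test = [ex for ex in examples if ex.sample_id == sid]
        train = [ex for ex in examples if ex.sample_id != sid]
        folds.append(CvFold(fold_id=f"loio-{sid}", train=deduplicate(train, test),
                            test=test, held_out_unit=sid))
    return folds


def _autosome_name(chrom: str) -> str | None:
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return c if c in AUTOSOMES else None


def split_loco(examples: list[LabeledExample], logger=None) -> list[CvFold]:
    """Leave-one-chromosome-out folds over autosomes 1–22.

    Non-autosomal examples (sex chromosomes, alt contigs) are excluded up
    front; the exclusion count is logged when a logger is supplied.
    Returns exactly 22 folds, one per autosome, possibly with empty test
    sets for autosomes absent from the data.
    """
    kept = [(ex, _autosome_name(ex.chrom)) for ex in examples]
    dropped = sum(1 for _, a in kept if a is None)
    if dropped and logger is not None:
        logger.warning("excluded %d non-autosomal examples from LOCO folds", dropped)
    autosomal = [(ex, a) for ex, a in kept if a is not None]
    folds = []
    for chrom in AUTOSOMES:
        test = [ex for ex, a in autosomal if a == chrom]
        train = [ex for ex, a in autosomal if a != chrom]
        folds.append(CvFold(fold_id=f"loco-chr{chrom}", train=deduplicate(train, test),
                            test=test, held_out_unit=chrom))
    return folds
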