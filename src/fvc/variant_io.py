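"""Read and write the standard variant-calling formats.

VCF records are normalized into :class:`VariantCall` objects — one per
(record, ALT allele) — so downstream code never sees multi-allelic sites
or caller-specific FORMAT layouts.  Alignments are summarized into
:class:`PileupContext` objects holding one entry per QC-passing read
overlapping the locus.

Coordinates are 1-based inclusive everywhere in the data model (the VCF
convention); BED inputs are 0-based half-open and converted at the
boundary by :func:`read_bed_intervals`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import pysam

SCORE_INFO_KEY = "FVC_SCORE"
FILTERED_TAG = "Filtered"

VALID_CALLERS = {"gatk", "mutect2", "varscan2", "deepvariant", "other"}

_ALLELE_CHARS = set("ACGTN")


class VcfFormatError(ValueError):
    """The input file is not a VCF this package can consume."""


class MultiSampleError(VcfFormatError):
    """Multi-sample VCFs are not supported; split per sample first."""


@dataclass(frozen=True)
class VariantCall:
    """One normalized variant call: a single ALT allele at a locus.

    ``pos`` is the 1-based position of the first REF base.  ``info`` and
    ``fmt`` carry the caller-emitted fields; allele-indexed fields
    (AD, AF) are pre-selected for this call's allele during decomposition
    and exposed as scalar ``AD_REF`` / ``AD_ALT`` / ``AF`` entries.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vtype: str  # "SNV" | "INDEL"
    qual: float | None = None
    info: dict = field(default_factory=dict)
    fmt: dict = field(default_factory=dict)
    sample_id: str = "sample"
    source_caller: str = "other"

    def __post_init__(self):
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if set(self.ref.upper()) - _ALLELE_CHARS or set(self.alt.upper()) - _ALLELE_CHARS:
            raise ValueError(f"alleles must be over ACGTN: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        expected = "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "INDEL"
        if self.vtype != expected:
            raise ValueError(f"vtype {self.vtype} inconsistent with alleles {self.ref}>{self.alt}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt, self.sample_id)


def variant_type(ref: str, alt: str) -> str:
    return "SNV" if len(ref) == 1 and len(alt) == 1 else "INDEL"


@dataclass(frozen=True)
class PileupRead:
    """Per-read evidence at the call locus."""

    supports_alt: bool
    supports_ref: bool
    base_quality: float  # phred; NaN for deletion-spanning reads
    mapping_quality: int
    forward_strand: bool
    dist_from_end: float  # distance of the variant from the nearer read end; NaN if unaligned


@dataclass
class PileupContext:
    """All QC-passing reads overlapping one call locus."""

    reads: list[PileupRead] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.reads)

    @property
    def alt_reads(self) -> list[PileupRead]:
        return [r for r in self.reads if r.supports_alt]

    @property
    def ref_reads(self) -> list[PileupRead]:
        return [r for r in self.reads if r.supports_ref]


def _scalar(value):
    """Collapse pysam's 1-tuples to scalars, keep everything else as-is."""
    if isinstance(value, tuple) and len(value) == 1:
        return value[0]
    return value


def _decompose_record(rec, sample_id: str, source_caller: str) -> Iterator[VariantCall]:
    sample = rec.samples[0] if rec.samples else None
    alts = rec.alts or ()
    for alt_index, alt in enumerate(alts):
        if alt is None or set(alt.upper()) - _ALLELE_CHARS:
            continue  # symbolic / spanning-deletion alleles are not point calls
        info = {}
        for key, value in rec.info.items():
            info[key] = _scalar(value)
        fmt: dict = {}
        if sample is not None:
            for key, value in sample.items():
                if key == "AD" and isinstance(value, (tuple, list)) and len(value) > alt_index:
                    ref_ad = value[0]
                    alt_ad = value[alt_index + 1] if len(value) > alt_index + 1 else None
                    if ref_ad is not None:
                        fmt["AD_REF"] = ref_ad
                    if alt_ad is not None:
                        fmt["AD_ALT"] = alt_ad
                elif key in ("AF", "VAF", "FREQ"):
                    v = value
                    if isinstance(v, (tuple, list)):
                        v = v[alt_index] if len(v) > alt_index else None
                    if isinstance(v, str) and v.endswith("%"):  # Varscan FREQ dialect
                        v = float(v[:-1]) / 100.0
                    if v is not None:
                        fmt["AF"] = float(v)
                else:
                    fmt[key] = _scalar(value)
        yield VariantCall(
            chrom=rec.chrom,
            pos=rec.pos,
            ref=rec.ref,
            alt=alt,
            vtype=variant_type(rec.ref, alt),
            qual=rec.qual,
            info=info,
            fmt=fmt,
            sample_id=sample_id,
            source_caller=source_caller,
        )


def read_vcf(path: str | Path, sample_id: str | None = None,
             source_caller: str = "other") -> list[VariantCall]:
    """Read a single-sample VCF into normalized per-allele calls.

    Multi-allelic records are decomposed into one :class:`VariantCall`
    per ALT allele with allele-specific AD/AF; record order is preserved.
    Multi-sample files are rejected — split them (e.g. ``bcftools view
    -s SAMPLE``) and run per sample.
    """
    if source_caller not in VALID_CALLERS:
        raise ValueError(f"source_caller must be one of {sorted(VALID_CALLERS)}")
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfFormatError(f"{path}: not a readable VCF: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        if len(samples) > 1:
            raise MultiSampleError(
                f"{path} has {len(samples)} samples; split the VCF into one file per "
                "sample (e.g. `bcftools view -s <sample>`) and filter each separately"
            )
        sid = sample_id or (samples[0] if samples else "sample")
        calls: list[VariantCall] = []
        for rec in vf:
            calls.extend(_decompose_record(rec, sid, source_caller))
    return calls


# alignment flags excluded from pileups: duplicate, secondary, supplementary, QC-fail
_EXCLUDE_FLAGS = 0x400 | 0x100 | 0x800 | 0x200


def _read_support(aln: pysam.AlignedSegment, call: VariantCall) -> PileupRead | None:
    """Classify one read's evidence at the call locus, or None if it skips it."""
    pos0 = call.pos - 1
    qpos = None
    indel_len = 0
    spans = False
    pairs = aln.get_aligned_pairs()
    for i, (q, r) in enumerate(pairs):
        if r == pos0:
            spans = True
            qpos = q
            # length of insertion immediately after this reference base
            j = i + 1
            while j < len(pairs) and pairs[j][1] is None and pairs[j][0] is not None:
                indel_len += 1
                j += 1
            # length of deletion immediately after this reference base
            if indel_len == 0:
                while j < len(pairs) and pairs[j][0] is None and pairs[j][1] is not None:
                    indel_len -= 1
                    j += 1
            break
    if not spans:
        return None

    ref_len, alt_len = len(call.ref), len(call.alt)
    if call.vtype == "SNV":
        base = aln.query_sequence[qpos] if qpos is not None else None
        supports_alt = base == call.alt and indel_len == 0
        supports_ref = base == call.ref and indel_len == 0
    elif alt_len > ref_len:  # insertion anchored at pos
        supports_alt = indel_len == alt_len - ref_len
        supports_ref = indel_len == 0 and qpos is not None
    else:  # deletion anchored at pos
        supports_alt = indel_len == -(ref_len - alt_len)
        supports_ref = indel_len == 0 and qpos is not None

    if qpos is not None:
        bq = float(aln.query_qualities[qpos]) if aln.query_qualities is not None else math.nan
        dist = float(min(qpos, aln.query_length - 1 - qpos))
    else:  # read carries a deletion over the locus
        bq = math.nan
        dist = math.nan
    return PileupRead(
        supports_alt=supports_alt,
        supports_ref=supports_ref,
        base_quality=bq,
        mapping_quality=aln.mapping_quality,
        forward_strand=not aln.is_reverse,
        dist_from_end=dist,
    )


def fetch_pileup(bam: str | Path | pysam.AlignmentFile,
                 reference: str | Path | None,
                 call: VariantCall,
                 window: int = 0) -> PileupContext:
    """Collect per-read support for ``call`` from a coordinate-sorted BAM.

    Reads flagged duplicate/secondary/supplementary/QC-fail are excluded.
    A region with no reads yields an empty context, not an error; an
    absent contig raises ``KeyError``.
    """
    own = False
    if not isinstance(bam, pysam.AlignmentFile):
        bam = pysam.AlignmentFile(str(bam), reference_filename=str(reference) if reference else None)
        own = True
    try:
        if call.chrom not in bam.references:
            raise KeyError(f"contig {call.chrom!r} not present in BAM")
        start0 = max(0, call.pos - 1 - window)
        end0 = call.pos + window
        reads = []
        for aln in bam.fetch(call.chrom, start0, end0):
            if aln.flag & _EXCLUDE_FLAGS or aln.is_unmapped:
                continue
            rec = _read_support(aln, call)
            if rec is not None:
                reads.append(rec)
        return PileupContext(reads=reads)
    finally:
        if own:
            bam.close()


def get_reference_window(fasta: str | Path | pysam.FastaFile, chrom: str,
                         pos: int, flank: int = 50) -> tuple[int, str]:
    """Return (1-based start, sequence) of the ±flank window around pos."""
    own = False
    if not isinstance(fasta, pysam.FastaFile):
        fasta = pysam.FastaFile(str(fasta))
        own = True
    try:
        start0 = max(0, pos - 1 - flank)
        end0 = pos + flank
        seq = fasta.fetch(chrom, start0, end0)
        return start0 + 1, seq.upper()
    finally:
        if own:
            fasta.close()


def read_bed_intervals(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read a BED file into 1-based inclusive intervals keyed by contig."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            out.setdefault(chrom, []).append((start0 + 1, end0))
    return out


def _build_output_header(calls: Sequence[VariantCall],
                         template: str | Path | None) -> pysam.VariantHeader:
    if template is not None:
        with pysam.VariantFile(str(template)) as vf:
            header = vf.header.copy()
    else:
        header = pysam.VariantHeader()
        seen = []
        for c in calls:
            if c.chrom not in seen:
                seen.append(c.chrom)
        for chrom in seen:
            header.contigs.add(chrom)
        if calls:
            header.add_sample(calls[0].sample_id)
    if SCORE_INFO_KEY not in header.info:
        header.info.add(SCORE_INFO_KEY, 1, "Float",
                        "Probability that the variant call is a true variant")
    if FILTERED_TAG not in header.filters:
        header.filters.add(FILTERED_TAG, None, None,
                           f"{SCORE_INFO_KEY} below the filtering threshold")
    return header


def write_filtered_vcf(calls: Sequence[VariantCall], scores: Sequence[float],
                       threshold: float = 0.5, out_path: str | Path = "out.vcf",
                       template: str | Path | None = None) -> Path:
    """Write calls with their truth probability and a PASS/Filtered verdict.

    Every record carries the score under INFO/``FVC_SCORE``; FILTER is set
    to ``Filtered`` iff score < threshold (strictly), else ``PASS``.  Any
    pre-existing FILTER value is overwritten.
    """
    if len(calls) != len(scores):
        raise ValueError("one score per call required")
    for s in scores:
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"score {s} outside [0, 1]")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")

    header = _build_output_header(calls, template)
    for call in calls:
        if call.chrom not in header.contigs:
            header.contigs.add(call.chrom)
    if header.samples and "GT" not in header.formats:
        header.formats.add("GT", 1, "String", "Genotype")
    out_path = Path(out_path)
    with pysam.VariantFile(str(out_path), "w", header=header) as out:
        for call, s in zip(calls, scores):
            rec = out.new_record(
                contig=call.chrom, start=call.pos - 1,
                alleles=(call.ref, call.alt),
                qual=call.qual,
            )
            rec.info[SCORE_INFO_KEY] = float(s)
            rec.filter.clear()
            rec.filter.add(FILTERED_TAG if s < threshold else "PASS")
            if header.samples:
                gt = call.fmt.get("GT")
                if gt is not None:
                    try:
                        rec.samples[0]["GT"] = gt
                    except (KeyError, ValueError):
                        pass
            out.write(rec)
    return out_path
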