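"""Synthetic data: labeled feature tables and tiny alignment fixtures.

Two generators make every stage testable without any download:

* :func:`simulate_feature_dataset` draws feature vectors from
  class-conditional distributions — Gaussian for unbounded features,
  logit-Gaussian for features bounded in [0, 1] — with the class-mean
  gap controlled by a single ``class_separation`` effect size.  Class
  imbalance is explicit (``n_true``/``n_false``) and reaches the extreme
  regimes real call sets show (thousands of true calls per false one).
  Labels are exact by construction.

* :func:`simulate_alignment_fixture` writes a small reference FASTA, a
  sorted+indexed BAM of 100 bp uniformly tiled reads with a requested
  alt-supporting fraction, and the matching single-sample VCF (plus a
  truth VCF and a manifest), so the VCF/BAM readers and the featurizer
  run on real formats with known expected values.

Neither generator claims biological realism of error profiles; they
exercise the contracts of the downstream modules.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pysam

from fvc.features import FEATURE_NAMES, FeatureVector
from fvc.truthset import LabeledExample
from fvc.variant_io import VariantCall

#: features that carry class signal, with per-feature (base mean, sd,
#: shift direction) on the latent (unbounded) scale
_INFORMATIVE = {
    "VAF": (0.0, 1.0, +1.0),        # latent logit scale
    "MBQ_ALT": (30.0, 4.0, +2.0),
    "MMQ": (55.0, 5.0, +2.0),
    "QUAL": (100.0, 40.0, +25.0),
    "QD": (10.0, 4.0, +2.0),
    "FS": (8.0, 4.0, -2.5),
    "SOR": (1.5, 0.7, -0.3),
    "MQ_RANKSUM": (0.0, 1.0, +0.5),
    "READPOS_RANKSUM": (0.0, 1.0, +0.5),
    "BASEQ_RANKSUM": (0.0, 1.0, +0.5),
}
_BOUNDED = {"VAF", "MQ0_FRAC", "STRAND_BALANCE", "GC_CONTENT"}
_RANKSUM_FEATURES = ("MQ_RANKSUM", "READPOS_RANKSUM", "BASEQ_RANKSUM")
_NONNEGATIVE = ("FS", "SOR", "QUAL", "QD", "DP", "AD_ALT", "MBQ_ALT", "MMQ",
                "HOMOPOLYMER_RUN", "REPEAT_UNITS", "MEDIAN_READPOS_ALT", "GQ")


@dataclass
class SimConfig:
    """Study conditions for the feature-table generator.

    Defaults emulate one leave-one-out unit of a germline call set:
    ~20k calls at 100:1 true:false imbalance across 4 individuals and
    the 22 autosomes, with a strong but imperfect class separation.
    """

    n_true: int = 19800
    n_false: int = 198
    class_separation: float = 2.0
    noise_scale: float = 1.0
    missing_rate: float = 0.10  # rank-sum and MBQ missingness
    n_samples: int = 4
    chromosomes: list[str] = field(default_factory=lambda: [str(i) for i in range(1, 23)])
    indel_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_true < 0 or self.n_false < 0:
            raise ValueError("class counts must be >= 0")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _draw_class(rng: np.random.Generator, n: int, is_true: bool,
                cfg: SimConfig) -> list[dict[str, float]]:
    sep = cfg.class_separation
    sign = +0.5 if is_true else -0.5
    cols: dict[str, np.ndarray] = {}

    dp = np.maximum(1, rng.poisson(30, size=n)).astype(float)
    cols["DP"] = dp
    cols["VARTYPE"] = (rng.random(n) < cfg.indel_fraction).astype(float)
    cols["GC_CONTENT"] = _logistic(rng.normal(0.0, 0.8 * cfg.noise_scale, n))
    cols["HOMOPOLYMER_RUN"] = rng.integers(1, 8, size=n).astype(float)
    cols["REPEAT_UNITS"] = np.where(cols["VARTYPE"] > 0,
                                    rng.integers(0, 6, size=n), 0).astype(float)
    for name, (mu, sd, direction) in _INFORMATIVE.items():
        shift = sign * sep * direction
        latent = rng.normal(mu + shift, sd * cfg.noise_scale, n)
        if name in _BOUNDED:
            cols[name] = _logistic(latent)
        else:
            cols[name] = latent
    cols["MQ0_FRAC"] = _logistic(rng.normal(-3.0, 0.8 * cfg.noise_scale, n))
    cols["STRAND_BALANCE"] = _logistic(rng.normal(0.0, 0.6 * cfg.noise_scale, n))
    cols["MEDIAN_READPOS_ALT"] = np.maximum(0, rng.normal(35, 12 * cfg.noise_scale, n))
    cols["GQ"] = np.clip(rng.normal(70, 20 * cfg.noise_scale, n), 0, 99)
    cols["AD_ALT"] = np.round(cols["VAF"] * dp)
    for name in _NONNEGATIVE:
        cols[name] = np.maximum(cols[name], 0.0)

    miss = {name: rng.random(n) < cfg.missing_rate
            for name in (*_RANKSUM_FEATURES, "MBQ_ALT")}
    rows = []
    for i in range(n):
        row = {name: float(cols[name][i]) for name in FEATURE_NAMES}
        for name, mask in miss.items():
            if mask[i]:
                row[name] = math.nan
        rows.append(row)
    return rows


def simulate_feature_dataset(cfg: SimConfig) -> list[LabeledExample]:
    """Draw a labeled, deterministic feature dataset under ``cfg``.

    The true:false ratio of the output equals n_true:n_false exactly;
    keys (chrom, pos, ref, alt, sample) are unique.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = [(r, True) for r in _draw_class(rng, cfg.n_true, True, cfg)]
    rows += [(r, False) for r in _draw_class(rng, cfg.n_false, False, cfg)]

    n = len(rows)
    chroms = [cfg.chromosomes[i % len(cfg.chromosomes)] for i in range(n)]
    samples = [f"S{1 + (i % max(1, cfg.n_samples))}" for i in range(n)]
    positions = rng.choice(np.arange(1_000, 50_000_000), size=n, replace=False)
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)

    out = []
    for i, (row, label) in enumerate(rows):
        ref = bases[ref_idx[i]]
        alt = bases[(ref_idx[i] + alt_shift[i]) % 4]
        if row["VARTYPE"] > 0:
            ref, alt = ref + "A" * int(1 + row["REPEAT_UNITS"] % 3), ref
            alt = ref[0]
        key = (chroms[i], int(positions[i]), str(ref), str(alt), samples[i])
        out.append(LabeledExample(key=key, features=FeatureVector(key=key, values=row),
                                  label=label))
    return out


@dataclass
class SiteSpec:
    """One planted variant site for an alignment fixture."""

    chrom: str = "ctg1"
    pos: int = 150  # 1-based
    ref: str = "C"
    alt: str = "T"
    depth: int = 30
    alt_fraction: float = 0.5
    base_quality: int = 30
    mapping_quality: int = 60
    alt_forward_fraction: float = 0.5
    is_true: bool = True

    def __post_init__(self):
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not (0.0 <= self.alt_fraction <= 1.0):
            raise ValueError("alt_fraction must be in [0, 1]")


READ_LENGTH = 100


def _contig_sequence(rng: np.random.Generator, site: SiteSpec, length: int) -> str:
    seq = rng.choice(list("ACGT"), size=length)
    pos0 = site.pos - 1
    seq[pos0:pos0 + len(site.ref)] = list(site.ref)
    return "".join(seq)


def _make_read(site: SiteSpec, contig: str, start0: int, name: str,
               carries_alt: bool, reverse: bool) -> pysam.AlignedSegment:
    pos0 = site.pos - 1
    ref_len, alt_len = len(site.ref), len(site.alt)
    a = pysam.AlignedSegment()
    a.query_name = name
    a.reference_id = 0
    a.reference_start = start0
    a.mapping_quality = site.mapping_quality
    a.flag = 16 if reverse else 0

    window = contig[start0:start0 + READ_LENGTH]
    if not carries_alt or site.ref == site.alt:
        seq = window
        cigar = [(0, len(seq))]
    elif ref_len == alt_len == 1:  # SNV
        off = pos0 - start0
        seq = window[:off] + site.alt + window[off + 1:]
        cigar = [(0, len(seq))]
    elif alt_len > ref_len:  # insertion after the anchor base
        off = pos0 - start0
        ins = site.alt[ref_len:]
        seq = window[:off + ref_len] + ins + window[off + ref_len:]
        seq = seq[:READ_LENGTH + len(ins)]
        cigar = [(0, off + ref_len), (1, len(ins)), (0, len(seq) - off - ref_len - len(ins))]
    else:  # deletion after the anchor base
        off = pos0 - start0
        dlen = ref_len - alt_len
        tail = contig[start0 + off + ref_len: start0 + off + ref_len + (READ_LENGTH - off - alt_len)]
        seq = window[:off + alt_len] + tail
        cigar = [(0, off + alt_len), (2, dlen), (0, len(seq) - off - alt_len)]
    a.query_sequence = seq
    a.query_qualities = pysam.qualitystring_to_array(
        chr(site.base_quality + 33) * len(seq))
    a.cigartuples = cigar
    return a


def simulate_alignment_fixture(site: SiteSpec, out_dir: str | Path,
                               seed: int = 0) -> dict[str, Path]:
    """Write a (FASTA, BAM, VCF) triple around one planted site.

    Reads tile the locus uniformly; exactly round(depth * alt_fraction)
    of them carry the alt allele and the requested fraction of alt reads
    is on the forward strand.  A truth VCF contains the site iff it is
    planted as true, and a manifest JSON records the full site spec.
    Returns the paths keyed by kind.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    contig_len = max(2 * READ_LENGTH + 100, site.pos + READ_LENGTH + 50)
    contig = _contig_sequence(rng, site, contig_len)

    fasta_path = out_dir / "ref.fa"
    fasta_path.write_text(f">{site.chrom}\n" + "\n".join(
        contig[i:i + 60] for i in range(0, len(contig), 60)) + "\n")
    pysam.faidx(str(fasta_path))

    n_alt = round(site.depth * site.alt_fraction)
    pos0 = site.pos - 1
    lo = max(0, pos0 - (READ_LENGTH - len(site.ref) - 5))
    hi = min(pos0, contig_len - READ_LENGTH - 10)
    starts = (np.linspace(lo, max(lo, hi), num=site.depth).astype(int)
              if site.depth else np.array([], dtype=int))

    n_alt_fwd = round(n_alt * site.alt_forward_fraction)
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": site.chrom, "LN": contig_len}]}
    bam_path = out_dir / "reads.bam"
    reads = []
    for i, start0 in enumerate(starts):
        carries_alt = i < n_alt
        reverse = (i >= n_alt_fwd) if carries_alt else (i % 2 == 1)
        reads.append(_make_read(site, contig, int(start0), f"read{i:04d}",
                                carries_alt, reverse))
    reads.sort(key=lambda r: r.reference_start)
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
        for r in reads:
            bam.write(r)
    pysam.index(str(bam_path))

    vcf_header = pysam.VariantHeader()
    vcf_header.contigs.add(site.chrom, length=contig_len)
    vcf_header.formats.add("GT", 1, "String", "Genotype")
    vcf_header.formats.add("DP", 1, "Integer", "Read depth")
    vcf_header.formats.add("AD", "R", "Integer", "Allelic depths")
    vcf_header.add_sample("sim")

    def write_vcf(path: Path, include_site: bool) -> Path:
        with pysam.VariantFile(str(path), "w", header=vcf_header) as vf:
            if include_site:
                rec = vf.new_record(contig=site.chrom, start=pos0,
                                    alleles=(site.ref, site.alt), qual=60)
                rec.samples[0]["GT"] = (0, 1)
                rec.samples[0]["DP"] = site.depth
                rec.samples[0]["AD"] = (site.depth - n_alt, n_alt)
                vf.write(rec)
        return path

    vcf_path = write_vcf(out_dir / "calls.vcf", True)
    truth_path = write_vcf(out_dir / "truth.vcf", site.is_true)

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(
        {"seed": seed, "site": asdict(site), "n_alt_reads": n_alt,
         "contig_length": contig_len}, indent=2))
    return {"fasta": fasta_path, "bam": bam_path, "vcf": vcf_path,
            "truth_vcf": truth_path, "manifest": manifest_path}
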