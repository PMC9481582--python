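import pytest

from fvc.simdata import SimConfig, SiteSpec, simulate_alignment_fixture, simulate_feature_dataset


@pytest.fixture(scope="session")
def snv_fixture(tmp_path_factory):
    """FASTA/BAM/VCF triple around one planted het SNV: depth 30, half the
    reads carrying the alt base."""
    out = tmp_path_factory.mktemp("snv_fixture")
    site = SiteSpec(chrom="ctg1", pos=150, ref="C", alt="T",
                    depth=30, alt_fraction=0.5)
    paths = simulate_alignment_fixture(site, out, seed=7)
    return site, paths


@pytest.fixture(scope="session")
def small_dataset():
    """2,200 labeled feature vectors at 10:1 imbalance, 4 samples, strong
    class separation."""
    cfg = SimConfig(n_true=2000, n_false=200, class_separation=2.0,
                    n_samples=4, seed=11)
    return simulate_feature_dataset(cfg)
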