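import numpy as np
import pytest

from hvrkit import ssv
from hvrkit.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small synthetic dataset shared across tests (read-only)."""
    config = SimulationConfig(
        seed=7,
        n_chromosomes=2,
        chrom_length_bp=2_000_000,
        mean_high_block_windows=12.0,
        mean_low_block_windows=25.0,
        n_genes=80,
        n_promoters=60,
        n_gwas_points=40,
    )
    return simulate_dataset(config, tmp_path_factory.mktemp("bundle"))


@pytest.fixture(scope="session")
def small_ssvs(small_bundle):
    """Query-vs-control SSV sets for every query strain of the small bundle."""
    layout = small_bundle.layout
    control = ssv.read_variants(small_bundle.paths["vcf_CTRL"], layout)
    out = {}
    for strain in ("Q1", "Q2", "Q3"):
        query = ssv.read_variants(small_bundle.paths[f"vcf_{strain}"], layout)
        out[strain] = ssv.call_ssvs_vs_control(query, control, label=strain)
    return out


def make_variant(chrom="chr1", pos=100, ref="A", alleles=("C",), zygosity=None):
    alleles = frozenset(alleles)
    if zygosity is None:
        zygosity = "hom" if len(alleles) == 1 else "het"
    return ssv.VariantRecord(chrom=chrom, pos=pos, ref=ref, alleles=alleles,
                             zygosity=zygosity)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
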