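import numpy as np
import pytest

from cranvar import SimulationConfig, simulate_genome, simulate_variant_panel


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=11,
        n_chroms=2,
        chrom_length=1_000_000,
        bin_size=250_000,
        background_rate=20.0,
        hotspot_fraction=0.0,
        shared_fraction=0.0,
        genes_per_chrom=50,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    genome, _ = simulate_genome(small_config)
    return genome


@pytest.fixture(scope="session")
def small_panel_vcf(small_config, small_genome, tmp_path_factory):
    path = tmp_path_factory.mktemp("panel") / "panel.vcf"
    _, truth = simulate_variant_panel(small_config, small_genome, vcf_path=str(path))
    return str(path), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
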