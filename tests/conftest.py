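import numpy as np
import pytest

from dhssremodel.simulate import SimConfig, write_bundle


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Reduced-scale generator config for fast end-to-end tests."""
    return SimConfig(
        seed=11,
        n_chroms=2,
        chrom_len=500_000,
        n_genes=40,
        n_repeats=600,
        n_enhancers=20,
        n_dhss_regions=60,
        n_tags_dhss=60_000,
        n_tags_cage=40_000,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config, tmp_path_factory):
    """A written synthetic input bundle shared across pipeline tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    return write_bundle(small_config, outdir)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
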