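import numpy as np
import pytest

from tatascan import AffinityModelConfig, fixtures


@pytest.fixture(scope="session")
def config() -> AffinityModelConfig:
    return AffinityModelConfig.default()


@pytest.fixture(scope="session")
def panel_odns():
    return fixtures.load_verification_panel()


@pytest.fixture(scope="session")
def panel_fixture(config):
    """Promoters + SNPs embedding the verification panel."""
    return fixtures.panel_promoters(config), fixtures.panel_snps()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
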