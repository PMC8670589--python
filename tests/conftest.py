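import numpy as np
import pytest

from plastcomp.simulate import GeneCatalogSpec, GeneratorConfig, generate_plastome

SMALL_CATALOG = GeneCatalogSpec(
    n_protein_coding=10, n_trna=5, n_rrna=2,
    ir_protein_coding=2, ir_trna=1, ir_rrna=1,
    protein_len_range=(150, 450), rrna_len_range=(300, 500),
)


def small_config(seed: int = 0, **kwargs) -> GeneratorConfig:
    base = dict(lsc_len=8000, ssc_len=2000, ir_len=2500, seed=seed, genes=SMALL_CATALOG)
    base.update(kwargs)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_genome():
    """A 15 kb synthetic plastome with known layout (session-cached)."""
    return generate_plastome(small_config(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n, gc=0.4):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])
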