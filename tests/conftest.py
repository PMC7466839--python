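import numpy as np
import pytest

from plastkit import (
    SyntheticSpec,
    mutate_species,
    synthesize_reference,
    tiny_spec,
)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def tiny_genome():
    """One deterministic 2 kbp synthetic plastome with truth."""
    spec = tiny_spec(seed=11)
    ref, truth = synthesize_reference(spec)
    return spec, ref, truth


@pytest.fixture(scope="session")
def small_comparative_set():
    """A reduced 20 kbp reference plus 4 derived species, with truth."""
    spec = SyntheticSpec(
        seed=5,
        length=20_000,
        lsc_len=12_000,
        ir_len=2_500,
        n_genes=10,
        n_tandems=40,
        n_ssrs=5,
        beta=5.0,
        n_species=4,
    )
    ref, truth = synthesize_reference(spec)
    species, truth = mutate_species(ref, truth, spec)
    return spec, ref, species, truth
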