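import numpy as np
import pytest

from gpsccd import (
    SubstitutionMatrix,
    build_training_set,
    default_calpain_profile,
    generate_benchmark,
)


@pytest.fixture(scope="session")
def blosum():
    return SubstitutionMatrix.blosum62()


@pytest.fixture(scope="session")
def small_benchmark():
    """Compact planted-motif benchmark shared by slower tests."""
    substrates, sites = generate_benchmark(
        n_substrates=12,
        length_range=(60, 120),
        sites_per_substrate_range=(1, 3),
        profile=default_calpain_profile(lam=1.0),
        rng_seed=7,
    )
    return substrates, sites


@pytest.fixture(scope="session")
def small_training_set(small_benchmark):
    substrates, sites = small_benchmark
    return build_training_set(substrates, sites, m=4, n=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_peptides(rng, count, length, pad_prob=0.05):
    """Random windows over the 21-symbol alphabet with occasional terminal '*' runs."""
    from gpsccd import AMINO_ACIDS, PAD

    peptides = []
    for _ in range(count):
        core = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        if rng.random() < pad_prob:
            k = int(rng.integers(1, length))
            core = PAD * k + core[k:]
        if rng.random() < pad_prob:
            k = int(rng.integers(1, length))
            core = core[: length - k] + PAD * k
        peptides.append(core)
    return peptides
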