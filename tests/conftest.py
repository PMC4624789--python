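import numpy as np
import pytest

from mitofounder import HVS1_RANGE, parse_variant_string


@pytest.fixture
def hap():
    """Shortcut: variant string -> Haplotype over the HVS-I range."""

    def build(text, **kw):
        return parse_variant_string(text, range=HVS1_RANGE, **kw)

    return build


@pytest.fixture
def rng():
    return np.random.default_rng(20151005)


def random_variant_string(rng, n_max=6):
    """A random, valid HVS-I variant string (substitutions only)."""
    k = int(rng.integers(0, n_max + 1))
    positions = rng.choice(np.arange(16051, 16401), size=k, replace=False)
    alleles = rng.choice(list("ACGT"), size=k)
    return " ".join(f"{p}{a}" for p, a in zip(positions, alleles))
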