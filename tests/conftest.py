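import numpy as np
import pandas as pd
import pytest

from admixsel.genodata import MISSING, GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_genotypes(rng, n_samples=12, n_variants=60, populations=("POP1", "POP2"),
                     missing_rate=0.1, n_chroms=2):
    """Random genotype matrix with missingness, several chromosomes."""
    calls = rng.integers(0, 3, size=(n_samples, n_variants)).astype(np.int8)
    calls[rng.random(calls.shape) < missing_rate] = MISSING
    per_chrom = n_variants // n_chroms + 1
    chrom = [f"chr{i // per_chrom + 1}" for i in range(n_variants)]
    pos = [(i % per_chrom + 1) * 1000 for i in range(n_variants)]
    pops = [populations[i % len(populations)] for i in range(n_samples)]
    return GenotypeMatrix.from_arrays(
        calls, chrom, pos, [f"s{i}" for i in range(n_samples)], pops
    )


@pytest.fixture
def toy_genotypes(rng):
    return random_genotypes(rng)
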