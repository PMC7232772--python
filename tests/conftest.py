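import numpy as np
import pytest

from ciscopop.genotypes import GenotypeMatrix, LocusTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def random_biallelic(rng, n_ind=50, n_loci=200, n_pops=2, missing=0.05,
                     maf_low=0.05):
    """Random bi-allelic matrix with missingness, used by round-trip tests."""
    p = rng.uniform(maf_low, 1 - maf_low, n_loci)
    dos = rng.binomial(2, p, size=(n_ind, n_loci)).astype(float)
    if missing:
        dos[rng.random((n_ind, n_loci)) < missing] = np.nan
    labels = [f"pop{1 + i * n_pops // n_ind}" for i in range(n_ind)]
    return GenotypeMatrix.from_dosage(dos, pop_labels=labels)


@pytest.fixture
def small_gm(rng):
    return random_biallelic(rng)


def gm_from_counts(counts_per_pop, n_loci=1):
    """Build a single-locus (or repeated) matrix from genotype counts.

    ``counts_per_pop`` is a list of dicts {0: nAA, 1: nAa, 2: naa} by pop.
    """
    dos, labels = [], []
    for pi, counts in enumerate(counts_per_pop):
        for d, n in counts.items():
            for _ in range(n):
                dos.append([float(d)] * n_loci)
                labels.append(f"pop{pi + 1}")
    return GenotypeMatrix.from_dosage(np.array(dos), pop_labels=labels)
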