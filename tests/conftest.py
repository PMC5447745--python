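import numpy as np
import pandas as pd
import pytest

from bsamap.synthetic_data import CrossConfig, simulate_f2, simulate_snp_map


@pytest.fixture(scope="session")
def small_cross() -> CrossConfig:
    """A compact cross for unit tests: 3 chromosomes, quick to simulate."""
    return CrossConfig(
        n_chromosomes=3,
        chrom_length_bp=500_000,
        snp_density=1e-4,
        n_f2=252,
        causal_chrom="chr2",
        causal_pos=250_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_snps(small_cross) -> pd.DataFrame:
    return simulate_snp_map(small_cross)


@pytest.fixture(scope="session")
def small_f2(small_cross, small_snps):
    return simulate_f2(small_cross, small_snps)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


GENO_CODES = np.array(["b", "h", "a"])  # P-allele dose 0, 1, 2


def simulate_pair(rng: np.random.Generator, n: int, r: float):
    """F2 genotype codes at two loci separated by recombination fraction r.

    Independent oracle for linkage estimation: each plant gets two gametes;
    each gamete picks a parental origin at locus 1 and flips it at locus 2
    with probability r (coupling-phase F1, no interference).
    """
    origin1 = rng.random((n, 2)) < 0.5
    rec = rng.random((n, 2)) < r
    origin2 = origin1 ^ rec
    dose1 = (origin1 == 0).sum(axis=1)
    dose2 = (origin2 == 0).sum(axis=1)
    return GENO_CODES[dose1], GENO_CODES[dose2]
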