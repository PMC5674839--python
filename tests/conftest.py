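import numpy as np
import pytest

from herdscan.genotype_io import GenotypeMatrix, SnpMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_gm(calls, positions=None, chrom=None, individuals=None, pops=None):
    """Small GenotypeMatrix builder for tests."""
    calls = np.asarray(calls, dtype=np.int8)
    n_ind, n_snp = calls.shape
    if positions is None:
        positions = np.arange(1, n_snp + 1) * 1000
    if chrom is None:
        chrom = [1] * n_snp
    if individuals is None:
        individuals = [f"ind{k}" for k in range(n_ind)]
    sm = SnpMap.from_arrays([f"snp{j}" for j in range(n_snp)], chrom, positions)
    gm = GenotypeMatrix(list(individuals), sm, calls)
    if pops is None:
        pops = {i: "POP" for i in individuals}
    return gm, pops


@pytest.fixture
def gm_builder():
    return make_gm
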