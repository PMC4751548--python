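import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from snparray import MISSING, SimConfig, make_genotype_set

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def toy_markers(n, chrom="1", start=1_000_000, step=1_000_000,
                alleles=("A", "G")):
    return pd.DataFrame({
        "name": [f"rs{i}" for i in range(n)],
        "chrom": chrom,
        "pos": [start + i * step for i in range(n)],
        "allele_A": alleles[0],
        "allele_B": alleles[1],
    })


def toy_gset(calls, chrom="1", alleles=("A", "G"), samples=None, **kw):
    calls = np.asarray(calls)
    markers = toy_markers(calls.shape[0], chrom=chrom, alleles=alleles)
    if samples is None:
        samples = [f"s{j}" for j in range(calls.shape[1])]
    return make_genotype_set(calls, markers, samples, **kw)


@pytest.fixture
def small_gset():
    """5 markers x 3 samples with every genotype class represented."""
    calls = np.array([
        [0, 1, 2],
        [1, 1, MISSING],
        [2, 0, 0],
        [MISSING, 2, 1],
        [0, 0, 2],
    ])
    return toy_gset(calls)


@pytest.fixture
def sim_config():
    return SimConfig(seed=42)
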