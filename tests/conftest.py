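import matplotlib

matplotlib.use("Agg")

import numpy as np
import pandas as pd
import pytest

from polyadapt import simulate as sim
from polyadapt.containers import FrequencyMatrix, GwasSummary


@pytest.fixture(scope="session")
def gradient_F():
    return sim.simulate_coancestry(6, model="gradient", depth=0.005, seed=11)


@pytest.fixture(scope="session")
def small_freqs(gradient_F):
    return sim.simulate_frequencies(gradient_F, 400, seed=12)


@pytest.fixture(scope="session")
def small_truth(small_freqs):
    return sim.make_truth(small_freqs, heritability=0.5, seed=13)


@pytest.fixture(scope="session")
def small_gwas(small_truth, small_freqs):
    return sim.simulate_gwas(small_truth, small_freqs, n_samples=50_000, seed=14)


def toy_frequency_matrix(freq, populations=None, **kwargs):
    """Build a FrequencyMatrix from a raw (pops x snps) array with stub metadata."""
    freq = np.asarray(freq, dtype=float)
    m, L = freq.shape
    populations = populations or [f"P{i}" for i in range(m)]
    snps = pd.DataFrame(
        {
            "chrom": ["1"] * L,
            "pos": np.arange(1, L + 1) * 1000,
            "snp": [f"s{i}" for i in range(L)],
            "a1": ["A"] * L,
            "a2": ["G"] * L,
        }
    )
    return FrequencyMatrix(freq=freq, populations=tuple(populations), snps=snps, **kwargs)


def toy_gwas(beta, snps=None, se=None, p=None):
    """GWAS table with given effects on A/G SNPs named s0, s1, ..."""
    beta = np.asarray(beta, dtype=float)
    L = beta.size
    se = np.full(L, 0.01) if se is None else np.asarray(se, dtype=float)
    p = np.full(L, 0.5) if p is None else np.asarray(p, dtype=float)
    df = pd.DataFrame(
        {
            "snp": [f"s{i}" for i in range(L)] if snps is None else snps,
            "chrom": ["1"] * L,
            "pos": np.arange(1, L + 1) * 1000,
            "a1": ["A"] * L,
            "a2": ["G"] * L,
            "beta": beta,
            "se": se,
            "p": p,
            "n": 10_000,
        }
    )
    return GwasSummary.from_dataframe(df)
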