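import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from cnvpath.data_io import GenotypeMatrix
from cnvpath.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_sim():
    """One default-scale synthetic dataset with every signal type planted."""
    cfg = SimConfig(seed=11, n_enriched_pathways=1, n_differentiated_cnvs=15,
                    n_functional_pairs=10)
    return simulate_all(cfg)


@pytest.fixture()
def tiny_genotypes():
    """Hand-built genotype matrix: 2 CNVs, 3 populations, some missing."""
    samples = [f"CEU{i}" for i in range(4)] + [f"YRI{i}" for i in range(4)] \
        + [f"ASN{i}" for i in range(2)]
    pop = pd.Series([s[:3] for s in samples], index=samples)
    cn = pd.DataFrame(
        [[2, 2, 2, 3, 2, 3, 3, 3, 2, 2],
         [5, 6, 7, 2, pd.NA, 2, 2, 2, 2, 2]],
        index=["cnv1", "cnv2"], columns=samples, dtype="Int64")
    return GenotypeMatrix(cn, pop)


def rand_freq_table(rng, n_cat=6):
    """Random frequency vectors and sizes for Fst oracle comparisons."""
    k = int(rng.integers(2, n_cat + 1))
    x = rng.dirichlet(np.ones(k))
    y = rng.dirichlet(np.ones(k))
    xf = np.zeros(n_cat)
    yf = np.zeros(n_cat)
    idx = rng.choice(n_cat, size=k, replace=False)
    xf[idx], yf[idx] = x, y
    nx = int(rng.integers(5, 300))
    ny = int(rng.integers(5, 300))
    return xf, yf, nx, ny
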