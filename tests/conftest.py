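import numpy as np
import pandas as pd
import pytest

import domvar


@pytest.fixture(scope="session")
def small_pedigree():
    """Three generations, 2 founders per mating, deterministic structure."""
    recs = [
        ("F1", 0, 0),
        ("F2", 0, 0),
        ("F3", 0, 0),
        ("F4", 0, 0),
        ("S1", "F1", "F2"),
        ("S2", "F1", "F2"),
        ("D1", "F3", "F4"),
        ("C1", "S1", "D1"),
        ("C2", "S1", "D1"),
        ("C3", "S2", "D1"),
    ]
    return domvar.Pedigree.from_parent_map(recs)


@pytest.fixture(scope="session")
def hwe_genotypes():
    """600 individuals x 120 SNPs simulated at Hardy-Weinberg proportions."""
    rng = np.random.default_rng(11)
    n, m = 600, 120
    p = rng.uniform(0.1, 0.5, m)
    codes = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    snp_map = pd.DataFrame(
        {
            "snp": [f"s{j}" for j in range(m)],
            "chrom": "1",
            "cm": np.arange(m, dtype=float),
            "bp": np.arange(1, m + 1) * 1000,
            "allele1": "A",
            "allele2": "B",
        }
    )
    ids = np.array([f"ind{i}" for i in range(n)], dtype=object)
    return domvar.GenotypeMatrix(codes, ids, snp_map)
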