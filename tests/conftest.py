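import numpy as np
import pandas as pd
import pytest

from envgp import EnvCovariateTable, MarkerMatrix, PhenotypeTable


@pytest.fixture
def small_phen() -> PhenotypeTable:
    """2 envs x 3 genotypes x 1 trait, balanced, no missing."""
    rows = []
    vals = iter([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    for env in ("E1", "E2"):
        for geno in ("G1", "G2", "G3"):
            rows.append((env, geno, "GY", next(vals)))
    return PhenotypeTable(pd.DataFrame(rows, columns=["env", "geno", "trait", "value"]))


@pytest.fixture
def small_markers() -> MarkerMatrix:
    rng = np.random.default_rng(11)
    vals = rng.integers(0, 3, size=(3, 8))
    vals[0, 0], vals[1, 0] = 0, 2  # guarantee polymorphism in the first column
    return MarkerMatrix(["G1", "G2", "G3"], [f"m{i}" for i in range(8)], vals)


@pytest.fixture
def small_covs() -> EnvCovariateTable:
    df = pd.DataFrame(
        {"tmax": [1.0, 2.0], "rain": [3.0, 1.0]}, index=["E1", "E2"]
    )
    return EnvCovariateTable(df)
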