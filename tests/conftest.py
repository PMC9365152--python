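import numpy as np
import pandas as pd
import pytest

from regmut.grid import WindowGrid, build_windows


@pytest.fixture(scope="session")
def small_grid() -> WindowGrid:
    """Two chromosomes, 3 + 2 windows of 1 Mbp."""
    return build_windows({"chr1": 3_000_000, "chr2": 2_500_000}, 1_000_000)


@pytest.fixture(scope="session")
def tiny_snvs() -> pd.DataFrame:
    """Hand-placed SNVs. Cohort A: two in chr1 window 0, one in chr1
    window 2; cohort B: one in chr1 window 1, one in chr2 window 0."""
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr1", "chr2"],
            "pos": [100, 200, 2_000_001, 1_500_000, 1],
            "ref": ["C", "C", "T", "G", "A"],
            "alt": ["T", "A", "C", "A", "G"],
            "sample_id": ["s1", "s1", "s2", "s2", "s3"],
            "cohort": ["A", "A", "A", "B", "B"],
        }
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    # function-scoped: a shared generator would make tests order-dependent
    return np.random.default_rng(20240901)
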