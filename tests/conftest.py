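import numpy as np
import pandas as pd
import pytest

from polkinetics.config import SimConfig
from polkinetics import simulate


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(seed=11, n_genes=30)


@pytest.fixture(scope="session")
def small_annotation(small_cfg):
    return simulate.make_annotation(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture()
def random_reads(rng) -> pd.DataFrame:
    n = 300
    starts = rng.integers(0, 9_800, size=n)
    lengths = rng.integers(20, 200, size=n)
    return pd.DataFrame({
        "chrom": "chr1",
        "start": starts,
        "end": np.minimum(starts + lengths, 10_000),
        "strand": rng.choice(["+", "-"], size=n),
    })
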