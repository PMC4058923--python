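import numpy as np
import pandas as pd
import pytest

from dynb.io import CountMatrix, SampleSheet
from dynb.normalization import SizeFactors, VarianceFunction


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def paper_design() -> SampleSheet:
    """2 conditions x 3 replicates x {0, 12, 24, 48, 72} h."""
    rows = [
        {
            "sample_id": f"{c}_{r}_t{int(t)}",
            "condition": c,
            "replicate": r,
            "time_h": float(t),
        }
        for c in ("Th0", "Th17")
        for r in ("r1", "r2", "r3")
        for t in (0, 12, 24, 48, 72)
    ]
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture
def small_counts(paper_design, rng) -> CountMatrix:
    n = len(paper_design.sample_ids)
    counts = rng.poisson(100.0, size=(8, n)) + 1
    return CountMatrix([f"g{i}" for i in range(8)], counts, paper_design.sample_ids)


@pytest.fixture
def unit_size_factors(paper_design) -> SizeFactors:
    ids = paper_design.sample_ids
    return SizeFactors(list(ids), np.ones(len(ids)))


@pytest.fixture
def modest_variance() -> VarianceFunction:
    return VarianceFunction(0.0, 1.0, 0.05)
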