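import numpy as np
import pandas as pd
import pytest

from mrtea import HarmonizedSet, SumStatsTable


def make_table(rows, name="trait", trait_type="continuous"):
    """Build a validated SumStatsTable from a list of row dicts."""
    defaults = {"chr": "1", "pos": 1000, "eaf": 0.3, "n": 10_000}
    full = []
    for i, row in enumerate(rows):
        r = {"snp": f"rs{i}", "ea": "A", "oa": "G", "beta": 0.1, "se": 0.01,
             "pval": 1e-9, **defaults, **row}
        full.append(r)
    return SumStatsTable.from_dataframe(pd.DataFrame(full), name, trait_type)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def homogeneous_set():
    """J=5 set where every Wald ratio is exactly 0.25."""
    bx = np.array([0.1, 0.2, 0.15, 0.12, 0.3])
    return HarmonizedSet.from_arrays(bx, np.full(5, 0.01), 0.25 * bx, np.full(5, 0.02))


def random_harmonized(rng, j=10, theta=0.2, seby=0.05, pleiotropy_sd=0.0):
    """Small synthetic harmonized set with known causal slope."""
    bx = rng.normal(0, 0.3, j)
    bx[np.abs(bx) < 0.02] += 0.05  # keep ratios well-conditioned
    alpha = rng.normal(0, pleiotropy_sd, j)
    by = theta * bx + alpha + rng.normal(0, seby, j)
    return HarmonizedSet.from_arrays(bx, np.full(j, 0.01), by, np.full(j, seby))
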