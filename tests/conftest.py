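import numpy as np
import pandas as pd
import pytest

from metamark import FeatureTable, SimulationSpec, normalize_chain, simulate_feature_table


@pytest.fixture
def tiny_raw_table() -> FeatureTable:
    """Two samples, three metabolites, no missing values."""
    intens = pd.DataFrame([[2.0, 3.0, 5.0], [1.0, 1.0, 2.0]],
                          index=["R1", "R2"], columns=["ma", "mb", "mc"])
    return FeatureTable(intens, pd.Series(["Control", "CSIS"],
                                          index=["R1", "R2"]))


@pytest.fixture
def two_group_tables():
    """Factory: (tss, tss_log10) pair of a simulated two-group experiment."""

    def make(n_per_group=7, n_metabolites=20, effects=None, seed=0,
             missing_rate=0.0, **kw):
        spec = SimulationSpec(n_per_group=n_per_group, groups=("A", "B"),
                              n_metabolites=n_metabolites,
                              effects=effects or {},
                              missing_rate=missing_rate, seed=seed, **kw)
        table, truth = simulate_feature_table(spec)
        tss, tlog = normalize_chain(table)
        return tss, tlog, truth

    return make


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
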