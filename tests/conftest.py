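import numpy as np
import pandas as pd
import pytest

from grslife import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_samples=1000, n_snps=300, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One shared synthetic dataset: (genotypes, truth, summary stats, cohort)."""
    return simulate_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)


def make_survival_frame(entry, exit_, event, sex=None, **covs) -> pd.DataFrame:
    df = pd.DataFrame({"entry_age": entry, "exit_age": exit_, "event": event})
    df["sex"] = sex if sex is not None else "female"
    for k, v in covs.items():
        df[k] = v
    df["sample_id"] = [f"S{i}" for i in range(len(df))]
    return df
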