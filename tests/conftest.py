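import numpy as np
import pandas as pd
import pytest

from bricdecay.simdata import SimConfig, simulate_truth, simulate_bric_counts

TIMES = np.array([0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 16.0])
TCOLS = ["t0", "t1", "t2", "t4", "t8", "t12", "t16"]


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_genes=300, dispersion=0.0, depth_per_timepoint=1e7, seed=42)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_truth(small_config)


@pytest.fixture(scope="session")
def small_counts(small_config, small_truth):
    return simulate_bric_counts(small_truth, small_config)


def make_tidy_counts(rows: dict[str, list[float]], condition="S2", replicate=1,
                     extra: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tidy count table from a {gene_id: 7 counts} mapping."""
    df = pd.DataFrame.from_dict(rows, orient="index", columns=TCOLS)
    df.index.name = "gene_id"
    df = df.reset_index()
    df.insert(1, "condition", condition)
    df.insert(2, "replicate", replicate)
    if extra is not None:
        df = pd.concat([df, extra], ignore_index=True)
    return df
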