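import numpy as np
import pandas as pd
import pytest

from lipidmets import AbundanceMatrix, CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down cohort used by most integration tests."""
    return CohortConfig(
        n_per_group=40,
        category_counts={"glycerolipid": 120, "glycerophospholipid": 40,
                         "sphingolipid": 20, "steroid": 10},
        effect_fraction=0.08,
        effect_log2fc=1.0,
        noise_sd=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


def make_matrix(values, group=None, scale="raw", prefix="f"):
    """Helper: AbundanceMatrix from a plain array (features x samples)."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    if group is None:
        group = [0] * (n_samp // 2) + [1] * (n_samp - n_samp // 2)
    cols = [f"s{i}" for i in range(n_samp)]
    df = pd.DataFrame(values, index=[f"{prefix}{i}" for i in range(n_feat)], columns=cols)
    return AbundanceMatrix(df, pd.Series(group, index=cols), scale)
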