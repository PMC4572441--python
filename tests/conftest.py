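import numpy as np
import pytest

from wcoxboost.datasets import SurvivalDataset


def random_dataset(seed, n=40, p=3, n_strata=2, censor=0.4):
    """Small random stratified dataset with continuous (tie-free) times."""
    rng = np.random.default_rng(seed)
    return SurvivalDataset(
        times=rng.exponential(1.0, n),
        status=(rng.uniform(size=n) > censor).astype(int),
        strata=rng.integers(1, n_strata + 1, n),
        covariates=rng.standard_normal((n, p)),
        covariate_names=[f"x{j}" for j in range(p)],
    )


@pytest.fixture
def tiny_dataset():
    # 8 observations, 2 strata, events in both
    return SurvivalDataset(
        times=[1.0, 2.0, 3.0, 4.0, 1.5, 2.5, 3.5, 4.5],
        status=[1, 0, 1, 1, 1, 1, 0, 1],
        strata=[1, 1, 1, 1, 2, 2, 2, 2],
        covariates=np.arange(16.0).reshape(8, 2) / 10.0,
        covariate_names=["a", "b"],
    )
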