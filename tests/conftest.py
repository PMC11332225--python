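import numpy as np
import pytest

from srttlearn.preprocess import baseline_normalize, flag_rt_outliers, summarize_blocks
from srttlearn.simulate import (
    DEFAULT_GROUP_PARAMS,
    CohortConfig,
    simulate_cohort,
)


def zero_noise_params(acc_p: float = 1.0):
    """Group parameter means with all randomness switched off."""
    params = {
        g: {k: (v[0], 0.0) for k, v in DEFAULT_GROUP_PARAMS[g].items()}
        for g in DEFAULT_GROUP_PARAMS
    }
    for g in params:
        params[g]["noise_sd"] = (0.0, 0.0)
        params[g]["outlier_rate"] = (0.0, 0.0)
        params[g]["acc_p"] = (acc_p, 0.0)
    return params


@pytest.fixture(scope="session")
def exp1_cohort():
    """Small noisy experiment-1 cohort (4 per group), shared across tests."""
    cfg = CohortConfig(experiment=1, n_per_group=4)
    return simulate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def exp1_products(exp1_cohort):
    trials, truth = exp1_cohort
    flagged = flag_rt_outliers(trials)
    blocks = summarize_blocks(flagged)
    norm = baseline_normalize(blocks)
    return {"trials": trials, "truth": truth, "flagged": flagged, "blocks": blocks, "norm": norm}


@pytest.fixture(scope="session")
def exp2_zero_noise():
    """Deterministic experiment-2 cohort: one participant per group, no noise."""
    cfg = CohortConfig(experiment=2, n_per_group=1, group_params=zero_noise_params())
    return simulate_cohort(cfg, seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
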