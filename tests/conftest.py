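import numpy as np
import pytest

from muvr2 import CausalSimSpec, run_causal_rank_experiment, simulate_signal_noise


@pytest.fixture(scope="session")
def causal_rank_summaries():
    """Median importance-rank summaries over 25 causal simulations.

    Computed once per session and shared between the acceptance tests and the
    covariate-adjustment tests: PLS and RF without covariates, and the elastic
    net under all three covariate-handling modes.
    """
    spec = CausalSimSpec()
    out = {
        "PLS": run_causal_rank_experiment(25, engines=("PLS",), modes=("C_none",),
                                     seed=11, spec=spec),
        "RF": run_causal_rank_experiment(25, engines=("RF",), modes=("C_none",),
                                    seed=11, spec=spec),
        "EN": run_causal_rank_experiment(25, engines=("EN",),
                                    modes=("C_none", "C_add", "C_keep"),
                                    seed=11, spec=spec),
    }
    return out


@pytest.fixture(scope="session")
def signal_dataset():
    """5 planted signals (3x noise SD) among 95 noise variables, n=60."""
    return simulate_signal_noise(60, 5, 95, 3.0, "regression", seed=17)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
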