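import numpy as np
import pytest

from eitrack import FilterConfig, make_step_scenario, run_filter, simulate


@pytest.fixture(scope="session")
def benchmark_record():
    """One realization of the two-segment benchmark scenario."""
    return simulate(make_step_scenario(seed=7))


@pytest.fixture(scope="session")
def benchmark_runs(benchmark_record):
    """Five filter runs (n_ens = 200, distinct seeds) on the shared record.

    Cached once per session; used by the accuracy and noise-recovery
    checks, matching the repeated-seed design of the validation study.
    """
    runs = []
    for seed in range(1, 6):
        cfg = FilterConfig.simulation(n_ens=200, seed=seed)
        runs.append(run_filter(benchmark_record.noisy_eeg, cfg))
    return runs


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
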