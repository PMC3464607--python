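import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sbscall as sc
from sbscall.params import CycleParams, ParameterSet

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


def det_lambda_params(L: int, w: int = 5) -> ParameterSet:
    """Default noisy preset with the density innovations switched off.

    sigma = 0 and d_var = 0 make the per-cluster density trajectory
    deterministic (lambda_t = (1 - d)^{t-1}), the regime in which exact
    forward inference over the discrete window chain is available.
    """
    base = sc.default_preset(L, w)
    cp = base.per_window[0]
    cp0 = CycleParams(
        d_mean=cp.d_mean,
        d_var=0.0,
        sigma_mean=0.0,
        sigma_var=0.0,
        alpha=cp.alpha,
        K=cp.K,
        Sigma=cp.Sigma,
    )
    return ParameterSet(base.phasing, (cp0,) * base.n_windows, w, L)


def det_lambda_path(params: ParameterSet) -> np.ndarray:
    d = params.per_window[0].d_mean
    return (1.0 - d) ** np.arange(params.L)


@pytest.fixture(scope="session")
def noiseless_params():
    return sc.noiseless_preset(L=30)


@pytest.fixture(scope="session")
def noiseless_tile(noiseless_params):
    return sc.simulate_tile(25, 30, noiseless_params, seed=1010)


@pytest.fixture(scope="session")
def default_params():
    return sc.default_preset(L=40)


@pytest.fixture(scope="session")
def default_tile(default_params):
    return sc.simulate_tile(60, 40, default_params, seed=31)


@pytest.fixture(scope="session")
def default_calls(default_params, default_tile):
    return sc.call_tile(default_tile.reads, default_params, N_p=400, seed=77)
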