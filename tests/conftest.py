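import warnings

import pytest

from secforce import BarrierParams, fit_global
from secforce.simulate import (
    PLATEAU_DURATIONS,
    REFERENCE_BARRIERS,
    REFERENCE_RATES,
    RipSimConfig,
    TraceSimConfig,
    simulate_rip_dataset,
    simulate_trace,
)

#: calibrated luminescence amplitude of the synthetic assay (RLU per imported fraction)
AMPLITUDE = 1.0e4


@pytest.fixture(scope="session")
def mtx_params() -> BarrierParams:
    return REFERENCE_BARRIERS["MTX"]


@pytest.fixture(scope="session")
def mn_params() -> BarrierParams:
    return REFERENCE_BARRIERS["M+N"]


@pytest.fixture(scope="session")
def table_rates() -> dict:
    return REFERENCE_RATES


@pytest.fixture(scope="session")
def mtx_events(mtx_params):
    """Synthetic MTX rip table at both pulling speeds (fixed seed)."""
    cfg = RipSimConfig(params=mtx_params, n_per_speed=(250, 250), seed=42, condition="MTX")
    return simulate_rip_dataset(cfg)


@pytest.fixture(scope="session")
def mtx_fit(mtx_events):
    """Bootstrap-calibrated global fit of the synthetic MTX rips."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_global(mtx_events, n_bootstrap=100, seed=7)


@pytest.fixture(scope="session")
def apo_trace():
    cfg = TraceSimConfig(rates=REFERENCE_RATES["apo"], condition="apo",
                         duration=PLATEAU_DURATIONS["apo"], seed=11)
    return simulate_trace(cfg)
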