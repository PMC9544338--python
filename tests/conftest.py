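import numpy as np
import pytest

from gtpkin import KineticParams, KineticTrace


@pytest.fixture
def wt_params() -> KineticParams:
    """Wild-type-like regime: equal binding and hydrolysis rates."""
    return KineticParams(k_bind=0.01, k_hydr=0.01, F_free=100.0, A=100.0, rho=0.2)


@pytest.fixture
def dead_params() -> KineticParams:
    """Hydrolysis-dead regime with fast binding."""
    return KineticParams(k_bind=0.05, k_hydr=0.0, F_free=100.0, A=100.0, rho=0.2)


def add_noise(trace: KineticTrace, sigma: float, rng: np.random.Generator) -> KineticTrace:
    return KineticTrace(
        trace.times,
        trace.signal + rng.normal(0.0, sigma, trace.signal.size),
        trace.assay_kind,
        injection_index=trace.injection_index,
        well_id=trace.well_id,
    )
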