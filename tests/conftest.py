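import numpy as np
import pytest

from sclerafit.poroelastic import (
    CLEParameters,
    LoadingProgram,
    SampleGeometry,
    StrainStep,
    simulate_response,
)


@pytest.fixture(scope="session")
def geometry() -> SampleGeometry:
    return SampleGeometry(radius=0.5e-3, thickness=200e-6)


@pytest.fixture(scope="session")
def treated_params() -> CLEParameters:
    # group-mean material truth used across recovery tests
    return CLEParameters(H_plus_A=104e3, H_minus_A=30e3, k=0.96e-14)


@pytest.fixture(scope="session")
def control_params() -> CLEParameters:
    return CLEParameters(H_plus_A=160e3, H_minus_A=30e3, k=0.73e-14)


@pytest.fixture(scope="session")
def single_step_program() -> LoadingProgram:
    return LoadingProgram(tare_load=0.0, steps=(StrainStep(0.05, 10.0, 1500.0),))


@pytest.fixture(scope="session")
def three_step_program() -> LoadingProgram:
    return LoadingProgram(tare_load=0.0)


@pytest.fixture(scope="session")
def single_step_trace(treated_params, geometry, single_step_program):
    return simulate_response(treated_params, geometry, single_step_program, sampling_rate=2.0)


def rel_rms(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a), np.asarray(b)
    return float(np.sqrt(np.mean((a - b) ** 2)) / np.max(np.abs(a)))
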