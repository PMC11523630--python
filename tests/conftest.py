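import numpy as np
import pytest

from spathe import ModelParameters, SystemState


@pytest.fixture(scope="session")
def defaults() -> ModelParameters:
    """Calibrated default parameter set (second-scenario life history)."""
    return ModelParameters()


@pytest.fixture(scope="session")
def random_prob_cases() -> list[tuple[float, float, float, int]]:
    """Reproducible batch of randomized (p_M, p_F, p_Y, N) visit settings."""
    rng = np.random.default_rng(20240917)
    cases = []
    for _ in range(30):
        raw = rng.dirichlet((1.0, 1.0, 1.0))
        n = int(rng.integers(1, 21))
        cases.append((float(raw[0]), float(raw[1]), float(raw[2]), n))
    return cases
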