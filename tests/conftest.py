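import numpy as np
import pytest

import qcniche as q


@pytest.fixture(scope="session")
def params():
    """A plain valid two-variable parameter set (not calibrated)."""
    return q.ParameterSet()


@pytest.fixture(scope="session")
def calibrated_alleviation():
    return q.default_parameters("alleviation")


@pytest.fixture(scope="session")
def calibrated_activation():
    return q.default_parameters("activation")


@pytest.fixture(scope="session")
def complex_params():
    return q.default_parameters("complex")


@pytest.fixture(scope="session")
def division_data():
    return q.OBSERVED_DIVISION_DATA


def draw_params(rng, base, complex_model=False):
    """Uniform [P0/2, 2*P0] draw around a base set, clipped to validity."""
    updates = {}
    for name in base.field_names():
        p0 = getattr(base, name)
        lo, hi = p0 / 2, 2 * p0
        if name == "eps_B":
            hi = min(hi, 1 - 1e-9)
        elif name == "eps_W":
            lo = max(lo, 1 + 1e-9)
        updates[name] = rng.uniform(lo, hi)
    return base.replace(**updates)
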