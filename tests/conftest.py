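import pytest

from chemodrift import Environment, MotorParams, PathwayParams


@pytest.fixture(scope="session")
def pw():
    return PathwayParams()


@pytest.fixture(scope="session")
def mp():
    return MotorParams()


@pytest.fixture(scope="session")
def mp_adapt():
    return MotorParams(adapt=True)


@pytest.fixture(scope="session")
def shallow():
    """Shallow exponential gradient, 1/g = 5000 µm."""
    return Environment(g=1.0 / 5000.0)


@pytest.fixture(scope="session")
def steep():
    """Steep exponential gradient, 1/g = 1000 µm."""
    return Environment(g=1.0 / 1000.0)
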