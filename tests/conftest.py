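import pytest

from lumitint.calibration import (
    build_grey_luminance_table,
    build_linearization_table,
    reference_curve,
)


@pytest.fixture(scope="session")
def curve():
    return reference_curve()


@pytest.fixture(scope="session")
def lum_table(curve):
    return build_grey_luminance_table(curve)


@pytest.fixture(scope="session")
def lin_table(curve):
    return build_linearization_table(curve)
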