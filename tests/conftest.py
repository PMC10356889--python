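import numpy as np
import pytest

from cbmndose import LQCurve, load_fixture

# published pooled calibration coefficients (c, alpha, beta) and their
# standard errors, by scoring mode
PRINTED_CURVES = {
    "fully-automated": ((0.0178, 0.0237, 0.0080), (0.0016, 0.0039, 0.0012)),
    "semi-automated": ((0.0096, 0.0170, 0.0111), (0.0011, 0.0031, 0.0010)),
    "manual": ((0.0197, 0.0259, 0.0135), (0.0018, 0.0045, 0.0014)),
}


def printed_curve(mode: str) -> LQCurve:
    (c, a, b), (sc, sa, sb) = PRINTED_CURVES[mode]
    cov = np.diag([sc**2, sa**2, sb**2])
    return LQCurve(c, a, b, sc, sa, sb, tuple(map(tuple, cov)),
                   {"label": mode, "max_dose": 4.0})


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1_fully_automated")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2_error_rates")


@pytest.fixture(scope="session")
def table3():
    return load_fixture("table3_contingency")


@pytest.fixture(scope="session")
def auto_curve():
    return printed_curve("fully-automated")


@pytest.fixture(scope="session")
def manual_curve():
    return printed_curve("manual")
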