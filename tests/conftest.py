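import numpy as np
import pytest

from msalimit import (
    GompertzParams,
    make_gompertz_lifetable,
    make_improving_series,
    make_loglinear_q_table,
)


@pytest.fixture
def loglinear_params():
    return GompertzParams(a=1e-4, b=0.1)


@pytest.fixture
def realistic_params():
    return GompertzParams(a=3e-5, b=0.1)


@pytest.fixture
def loglinear_table(loglinear_params):
    return make_loglinear_q_table(loglinear_params, max_age=110)


@pytest.fixture
def gompertz_table(realistic_params):
    return make_gompertz_lifetable(realistic_params, max_age=110)


@pytest.fixture
def improving_series():
    """Short improving sequence of exact period tables (1%/yr decline)."""
    return make_improving_series(
        GompertzParams(5e-5, 0.1), 0.01, range(1950, 1981), max_age=110
    )
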