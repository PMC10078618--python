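import pytest

from evpem.io import load_fixtures
from evpem.response import ResponseCoefficients


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def coeffs():
    return ResponseCoefficients.default()


@pytest.fixture(scope="session")
def zero_coeffs():
    """A coefficient set with all rates and soil-change terms zeroed."""
    zero_quad = {"basis": "quadratic", "a": 0.0, "b": 0.0, "c": 0.0}
    zero_log = {"basis": "semilog", "slope": 0.0, "intercept": 0.0}
    regimes = {"submerged": zero_quad, "exposed": zero_log, "extended_exposed": zero_log}
    return ResponseCoefficients.from_dict(
        {
            "k_ag": regimes,
            "k_bg": regimes,
            "delta_st": regimes,
            "anpp": {"slope": -177.4, "intercept": 696.5},
            "bnpp": {"a": -0.4, "b": 3.5, "c": 78.9},
        }
    )
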