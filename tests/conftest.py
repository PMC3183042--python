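import numpy as np
import pytest

from sexmig import ConventionConfig, ObservedPattern, ParameterGrid


@pytest.fixture(scope="session")
def default_conventions() -> ConventionConfig:
    return ConventionConfig()


@pytest.fixture(scope="session")
def default_grid() -> ParameterGrid:
    return ParameterGrid()


@pytest.fixture(scope="session")
def reference_patterns() -> dict[str, ObservedPattern]:
    """The six canonical incongruence patterns analysed in the model study:
    mito vs Y, mito vs autosomes (1 and 5 loci), Y vs autosomes (1 and 5
    short loci), and 10 X vs 30 autosomal loci."""
    make = ObservedPattern.from_counts
    return {
        "mt_short_y_long": make([("MT", "short", 1), ("Y", "long", 1)]),
        "mt_short_a_long": make([("MT", "short", 1), ("A", "long", 1)]),
        "mt_short_a_long5": make([("MT", "short", 1), ("A", "long", 5)]),
        "y_long_a_short": make([("Y", "long", 1), ("A", "short", 1)]),
        "y_long_a_short5": make([("Y", "long", 1), ("A", "short", 5)]),
        "x_short10_a_long30": make([("X", "short", 10), ("A", "long", 30)]),
    }


@pytest.fixture(scope="session")
def oracle_grid() -> list[tuple[float, str]]:
    """(2Nm, marker) cells on which chain, CTMC and Monte Carlo are compared."""
    return [(two_nm, mk) for two_nm in (0.1, 1.0, 5.0) for mk in ("A", "MT", "Y")]


@pytest.fixture(autouse=True)
def _no_boundary_warnings_noise():
    """CI-touches-boundary warnings are expected for weak patterns; keep
    test output clean without hiding other warnings."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="95% CI region touches the 2Nm grid boundary"
        )
        yield


def rng_for(name: str) -> np.random.Generator:
    """Stable per-test RNG so tests are order-independent."""
    return np.random.default_rng(abs(hash(name)) % 2**31)
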