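import numpy as np
import pytest

from gridcode import ScaleSystem


@pytest.fixture(scope="session")
def sigma2():
    """Two modules with the golden scale ratio, the optimal M=2 system."""
    return ScaleSystem.from_symbolic(["1", "phi"])


@pytest.fixture(scope="session")
def sigma3():
    """Golden geometric triple {1, sigma, sigma^2} (degenerate: order 2 < M)."""
    return ScaleSystem.from_symbolic(["1", "phi", "phi^2"])


@pytest.fixture(scope="session")
def cbrt3():
    """Powers of 2^(1/3): a third-order algebraic triple, badly approximable."""
    return ScaleSystem.from_symbolic(["1", "2^(1/3)", "2^(2/3)"])


@pytest.fixture(scope="session")
def rational2():
    """Scales {1, 3/2}: exact interference at distance 3."""
    return ScaleSystem((1.0, 1.5))


def random_system(rng: np.random.Generator, M: int,
                  lo: float = 1.05, hi: float = 2.0) -> ScaleSystem:
    upper = np.sort(rng.uniform(lo, hi, M - 1))
    while len(upper) > 1 and np.min(np.diff(upper)) < 1e-3:
        upper = np.sort(rng.uniform(lo, hi, M - 1))
    return ScaleSystem((1.0, *map(float, upper)))
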