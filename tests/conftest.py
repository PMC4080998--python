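import numpy as np
import pytest

from foodtrace import SalesMatrix, fixture, to_consumption_model


@pytest.fixture(scope="session")
def disjoint_sales():
    return fixture("disjoint")


@pytest.fixture(scope="session")
def identical_pair_sales():
    return fixture("identical_pair")


@pytest.fixture(scope="session")
def clustered_sales():
    return fixture("clustered")


@pytest.fixture(scope="session")
def paper_like_sales():
    return fixture("paper_like")


@pytest.fixture
def toy_sales():
    """3 products x 3 regions with hand-checkable overlap structure."""
    return SalesMatrix(
        ["k", "l", "j"],
        ["a", "b", "c"],
        np.array([[4.0, 0.0, 0.0],
                  [2.0, 2.0, 0.0],
                  [1.0, 1.0, 2.0]]),
    )


@pytest.fixture
def toy_model(toy_sales):
    return to_consumption_model(toy_sales)


def random_sales(n_products: int, n_regions: int, seed: int) -> SalesMatrix:
    """Dense random matrix with strictly positive row sums."""
    rng = np.random.default_rng(seed)
    values = rng.gamma(1.0, 10.0, size=(n_products, n_regions))
    values[rng.random(values.shape) < 0.3] = 0.0
    values[values.sum(axis=1) == 0, 0] = 1.0
    return SalesMatrix([f"p{i}" for i in range(n_products)],
                       [f"r{j}" for j in range(n_regions)], values)
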